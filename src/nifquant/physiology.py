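"""Culture physiology: growth rates, ammonium assay, acetylene reduction.

Nitrogenase activity is measured by the acetylene reduction assay:
nitrogenase reduces acetylene to ethylene, which accumulates in the sealed
culture headspace and is quantified by GC.  Headspace sampling dilutes both
gases equally, so the ethylene signal is corrected by the concomitant
dilution of the (otherwise constant) acetylene signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GrowthRate:
    rate_per_h: float
    doublings_per_h: float
    window: tuple[float, float]


def growth_rate(
    times_h: Sequence[float],
    od600: Sequence[float],
    window: tuple[float, float] | None = None,
) -> GrowthRate:
    """Specific growth rate ln(OD2/OD1)/(t2-t1) between the first and last
    observation inside ``window`` (whole series by default)."""
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, od = t[mask], od[mask]
    if len(t) < 2:
        raise ValueError("need at least 2 points in window")
    if np.any(od <= 0):
        raise ValueError("OD values must be > 0")
    rate = math.log(od[-1] / od[0]) / (t[-1] - t[0])
    return GrowthRate(rate, rate / math.log(2), (float(t[0]), float(t[-1])))


@dataclass(frozen=True)
class NH4Curve:
    """Linear absorbance-vs-concentration calibration for the colorimetric
    ammonium assay (standards typically spanning 78-5000 uM)."""

    slope: float          # absorbance per uM
    intercept: float
    conc_min_um: float
    conc_max_um: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("inverted or flat calibration curve")


def fit_nh4_curve(standards: Sequence[tuple[float, float]]) -> NH4Curve:
    """Fit the assay curve from (concentration uM, absorbance) standards."""
    if len(standards) < 2:
        raise ValueError("need at least 2 standards")
    conc = np.array([c for c, _ in standards], dtype=float)
    ab = np.array([a for _, a in standards], dtype=float)
    fit = stats.linregress(conc, ab)
    return NH4Curve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        conc_min_um=float(conc.min()),
        conc_max_um=float(conc.max()),
        r_squared=float(fit.rvalue**2),
    )


@dataclass(frozen=True)
class NH4Result:
    concentration_um: float
    censored: bool = False   # below the lowest standard; report as "< min"

    def __str__(self) -> str:
        if self.censored:
            return f"< {self.concentration_um:g} uM"
        return f"{self.concentration_um:g} uM"


def nh4_from_absorbance(abs690: float, curve: NH4Curve) -> NH4Result:
    """Interpolate NH4+ concentration; sub-range readings are censored at
    the lowest standard rather than extrapolated."""
    conc = (abs690 - curve.intercept) / curve.slope
    if conc < curve.conc_min_um:
        return NH4Result(curve.conc_min_um, censored=True)
    return NH4Result(conc, censored=False)


def correct_gas_dilution(
    ethylene_areas: Sequence[float], acetylene_areas: Sequence[float]
) -> np.ndarray:
    """Rescale ethylene areas for headspace sampling losses using the
    concomitant dilution of acetylene: corrected(t) = E(t) * A(0)/A(t)."""
    eth = np.asarray(ethylene_areas, dtype=float)
    acet = np.asarray(acetylene_areas, dtype=float)
    if np.any(acet <= 0):
        raise ValueError("acetylene areas must be > 0")
    return eth * acet[0] / acet


def acetylene_reduction_rate(
    times_h: Sequence[float],
    ethylene_areas: Sequence[float],
    acetylene_areas: Sequence[float],
    od600: Sequence[float],
    nmol_per_area: float,
    culture_volume_ml: float,
) -> pd.DataFrame:
    """Interval rates of ethylene production, nmol OD^-1 mL^-1 h^-1.

    The corrected cumulative ethylene signal is converted to nmol via the
    GC calibration factor; each interval's rate is normalised by the OD at
    the interval end and the culture volume.
    """
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    corrected = correct_gas_dilution(ethylene_areas, acetylene_areas)
    nmol = corrected * nmol_per_area
    rows = []
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        rate = (nmol[i] - nmol[i - 1]) / dt / (od[i] * culture_volume_ml)
        rows.append(
            {
                "t_start_h": t[i - 1],
                "t_end_h": t[i],
                "ethylene_nmol": nmol[i],
                "rate_nmol_per_od_ml_h": rate,
            }
        )
    return pd.DataFrame(rows)
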