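"""Absolute amino-acid quantification and pool fold-change statistics.

Concentrations are read off external standard curves (least-squares lines
through a dilution series of an amino-acid standard mix), scaled through
the extraction-volume chain and the OD-specific cell count, and converted
to intracellular molarity assuming a fixed 1-fL cell volume.  Pool
dynamics are summarised as fold changes against each amino acid's base
mean (the mean of per-time-point means across the whole time course), with
one-sample t-tests against the base mean within a strain and two-sample
t-tests (Benjamini-Hochberg adjusted) between strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import DEFAULT_CONSTANTS, PhysiologyConstants


@dataclass(frozen=True)
class StandardCurve:
    """External calibration line for one analyte: area = slope*conc + intercept."""

    analyte: str
    levels: tuple[tuple[float, float], ...]   # (concentration uM, area)
    slope: float
    intercept: float
    r_squared: float
    loq_um: float

    def concentration(self, area: float) -> float:
        """Back-calculated concentration (uM) for an observed area."""
        return (area - self.intercept) / self.slope


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    analyte: str = "",
    accuracy_tolerance: float = 0.20,
    r_squared_min: float = 0.99,
) -> StandardCurve:
    """Fit a standard curve and locate the limit of quantitation.

    The line is fitted by least squares; if the fit is non-linear at the
    low end (poor r^2 or a level back-calculating outside +/-20% of
    nominal), the lowest levels are dropped one at a time until the
    remaining region is linear.  The LOQ is the lowest retained level.
    """
    pts = sorted((float(c), float(a)) for c, a in levels)
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration levels")
    concs = np.array([c for c, _ in pts])
    if concs.max() <= 0 or concs.max() / max(concs.min(), 1e-300) < 10:
        raise ValueError("levels must span at least one order of magnitude")

    lo = 0
    while True:
        sub = pts[lo:]
        c = np.array([p[0] for p in sub])
        a = np.array([p[1] for p in sub])
        if len(sub) < 3 or np.allclose(c, c[0]):
            raise ValueError(f"{analyte or 'analyte'}: no linear region found")
        fit = stats.linregress(c, a)
        r2 = float(fit.rvalue**2)
        if fit.slope != 0:
            back = (a - fit.intercept) / fit.slope
            accurate = np.all(np.abs(back - c) <= accuracy_tolerance * c)
        else:
            accurate = False
        if r2 >= r_squared_min and accurate:
            return StandardCurve(
                analyte=analyte,
                levels=tuple(pts),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=r2,
                loq_um=float(c[0]),
            )
        lo += 1


@dataclass(frozen=True)
class MetaboliteSampleMeta:
    """Extraction metadata for the per-cell conversion of amino-acid pools."""

    sample_id: str
    strain: str
    time_h: float
    od600: float
    replicate: int = 1
    culture_volume_ml: float = 15.0
    extract_volume_ul: float = 100.0
    derivatisation_dilution: float = 1.0   # extract conc / injected conc

    def cells_in_extract(
        self, constants: PhysiologyConstants = DEFAULT_CONSTANTS
    ) -> float:
        return self.od600 * self.culture_volume_ml * constants.cells_per_od_ml


@dataclass(frozen=True)
class AminoAcidPool:
    amino_acid: str
    sample_id: str
    intracellular_molar: float
    molecules_per_cell: float
    below_loq: bool = False


def molecules_per_cell_from_molar(
    intracellular_molar: float,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> float:
    """Molecules per cell at a given intracellular molarity (1-fL cell)."""
    return intracellular_molar * constants.cell_volume_l * constants.avogadro


def quantify_amino_acids(
    areas: Mapping[str, float],
    curves: Mapping[str, StandardCurve],
    meta: MetaboliteSampleMeta,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> list[AminoAcidPool]:
    """Convert one sample's peak areas to intracellular pools.

    Values back-calculating below an analyte's LOQ are flagged, not dropped.
    """
    cells = meta.cells_in_extract(constants)
    if cells <= 0:
        raise ValueError("zero cells in extract")
    pools: list[AminoAcidPool] = []
    for analyte, area in sorted(areas.items()):
        curve = curves.get(analyte)
        if curve is None:
            raise KeyError(f"no standard curve for {analyte!r}")
        conc_injected_um = curve.concentration(area)
        conc_extract_um = conc_injected_um * meta.derivatisation_dilution
        moles = conc_extract_um * 1e-6 * meta.extract_volume_ul * 1e-6
        intracellular = moles / (cells * constants.cell_volume_l)
        pools.append(
            AminoAcidPool(
                amino_acid=analyte,
                sample_id=meta.sample_id,
                intracellular_molar=intracellular,
                molecules_per_cell=moles * constants.avogadro / cells,
                below_loq=conc_injected_um < curve.loq_um,
            )
        )
    return pools


def pools_to_frame(
    pools: Sequence[AminoAcidPool], metas: Mapping[str, MetaboliteSampleMeta]
) -> pd.DataFrame:
    rows = []
    for p in pools:
        meta = metas[p.sample_id]
        rows.append(
            {
                "amino_acid": p.amino_acid,
                "sample_id": p.sample_id,
                "strain": meta.strain,
                "time_h": meta.time_h,
                "replicate": meta.replicate,
                "concentration_m": p.intracellular_molar,
                "molecules_per_cell": p.molecules_per_cell,
                "below_loq": p.below_loq,
            }
        )
    return pd.DataFrame(rows)


def _ttest_1samp(values: np.ndarray, popmean: float) -> float:
    if len(values) < 2:
        return math.nan
    if np.ptp(values) == 0:
        # identical replicates: degenerate t-test, p -> 0 unless equal to mean
        return 1.0 if values[0] == popmean else 0.0
    return float(stats.ttest_1samp(values, popmean).pvalue)


def _ttest_2samp(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return math.nan
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b).pvalue)


def base_mean_fold_changes(
    df: pd.DataFrame, value: str = "concentration_m"
) -> pd.DataFrame:
    """Per-amino-acid fold change of each time point against the base mean.

    The base mean is the mean of per-time-point means across all time
    points, so the fold changes of any amino acid average to exactly 1.
    Includes a one-sample t-test of the replicate values at each time point
    against the base mean.
    """
    rows = []
    for aa, sub in df.groupby("amino_acid"):
        per_time = sub.groupby("time_h")[value].mean()
        base = per_time.mean()
        if base == 0:
            raise ValueError(f"zero base mean for {aa!r}")
        for t, m in per_time.items():
            reps = sub.loc[sub["time_h"] == t, value].to_numpy()
            rows.append(
                {
                    "amino_acid": aa,
                    "time_h": t,
                    "mean": m,
                    "base_mean": base,
                    "fold_change": m / base,
                    "p_value": _ttest_1samp(reps, base),
                }
            )
    return pd.DataFrame(rows)


def strain_contrast(
    df: pd.DataFrame,
    test_strain: str,
    reference_strain: str,
    value: str = "concentration_m",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mutant-vs-reference fold change per amino acid per time point.

    Two-sample t-tests with Benjamini-Hochberg adjustment across the full
    amino acid x time grid of the contrast.
    """
    rows = []
    test = df[df["strain"] == test_strain]
    ref = df[df["strain"] == reference_strain]
    for (aa, t), sub in test.groupby(["amino_acid", "time_h"]):
        r = ref[(ref["amino_acid"] == aa) & (ref["time_h"] == t)]
        if r.empty:
            continue
        a = sub[value].to_numpy()
        b = r[value].to_numpy()
        ref_mean = b.mean()
        rows.append(
            {
                "amino_acid": aa,
                "time_h": t,
                "fold_change": a.mean() / ref_mean if ref_mean else math.inf,
                "p_value": _ttest_2samp(a, b),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    mask = out["p_value"].notna()
    adjusted = np.full(len(out), math.nan)
    if mask.any():
        adjusted[mask.to_numpy()] = multipletests(
            out.loc[mask, "p_value"], method="fdr_bh"
        )[1]
    out["p_adjusted"] = adjusted
    out["significant"] = out["p_adjusted"] < alpha
    return out
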