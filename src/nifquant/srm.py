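"""Isotope-dilution SRM quantification.

Converts transition-level integrated peak areas into absolute protein
copies per cell.  The heavy-labelled QconCAT standard is spiked at a known
concentration, so the light/heavy (sample/standard) peak-area ratio scales
the known standard amount to the endogenous peptide amount.  Peptide
amounts roll up to protein copy number via the prep-volume chain and the
OD-specific plating density; modification occupancy is the modified/total
light-area ratio of the modifiable peptide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_CONSTANTS, PhysiologyConstants

REQUIRED_REPORT_COLUMNS = (
    "sample_id",
    "peptide",
    "product_ion",
    "label_state",
    "modification_state",
    "area",
)


@dataclass(frozen=True)
class PeakMeasurement:
    """One integrated transition peak in one sample."""

    sample_id: str
    peptide: str
    product_ion: str
    label_state: str           # light | heavy
    modification_state: str    # none | +UMP
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"negative area for {self.peptide}/{self.product_ion}")


@dataclass(frozen=True)
class SampleMeta:
    """Sample prep metadata needed for the per-cell conversion chain."""

    sample_id: str
    strain: str
    time_h: float
    od600: float
    replicate: int = 1
    culture_volume_ml: float = 15.0
    resuspension_volume_ul: float = 500.0
    aliquot_volume_ul: float = 30.0
    digest_volume_ul: float = 300.0
    standard_concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "culture_volume_ml",
            "resuspension_volume_ul",
            "aliquot_volume_ul",
            "digest_volume_ul",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.od600 < 0:
            raise ValueError("od600 must be >= 0")

    def cells_in_digest(
        self, constants: PhysiologyConstants = DEFAULT_CONSTANTS
    ) -> float:
        """Cells represented in the digested aliquot."""
        return (
            self.od600
            * self.culture_volume_ml
            * constants.cells_per_od_ml
            * (self.aliquot_volume_ul / self.resuspension_volume_ul)
        )


def parse_report(
    table: pd.DataFrame | str | Path,
    known_peptides: set[str] | None = None,
) -> list[PeakMeasurement]:
    """Parse a transition-level peak-area report (CSV path or DataFrame).

    Unknown peptides are retained with a warning; negative areas and missing
    columns are errors.
    """
    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table
    missing = [c for c in REQUIRED_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report missing columns: {missing}")
    records: list[PeakMeasurement] = []
    for idx, row in df.iterrows():
        if row["area"] < 0:
            raise ValueError(f"negative area at row {idx}")
        if known_peptides is not None and row["peptide"] not in known_peptides:
            warnings.warn(f"unknown peptide {row['peptide']!r} at row {idx}",
                          stacklevel=2)
        records.append(
            PeakMeasurement(
                sample_id=str(row["sample_id"]),
                peptide=str(row["peptide"]),
                product_ion=str(row["product_ion"]),
                label_state=str(row["label_state"]),
                modification_state=str(row["modification_state"]),
                area=float(row["area"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# calibration / transition validation

@dataclass(frozen=True)
class CalibrationParams:
    r_squared_threshold: float = 0.98
    lod_limit_nm: float = 1.0
    min_levels: int = 4


@dataclass(frozen=True)
class CalibrationResult:
    peptide: str
    product_ion: str
    slope: float
    intercept: float
    r_squared: float
    lod_nm: float
    usable: bool
    reason: str = ""


def validate_linearity(
    dilutions: Sequence[float],
    light_areas: Sequence[float],
    heavy_areas: Sequence[float],
    blank_areas: Sequence[float],
    analyte_conc_nm: float,
    peptide: str = "",
    product_ion: str = "",
    params: CalibrationParams | None = None,
) -> CalibrationResult:
    """Assess one transition on a dilution series of cell extract.

    The light/heavy area ratio is regressed on the dilution factor (the
    spiked standard is constant, so the ratio should be proportional to the
    extract dilution).  The LOD is the lowest assayed concentration
    (``analyte_conc_nm`` x dilution) whose fitted light signal exceeds the
    blank mean + 3 x blank SD.  A transition is usable when the fit is
    linear (r^2 >= threshold) and the LOD is at or below the limit.
    """
    params = params or CalibrationParams()
    if len(dilutions) < params.min_levels:
        return CalibrationResult(
            peptide, product_ion, math.nan, math.nan, math.nan, math.inf,
            usable=False, reason=f"fewer than {params.min_levels} dilution levels",
        )
    d = np.asarray(dilutions, dtype=float)
    light = np.asarray(light_areas, dtype=float)
    heavy = np.asarray(heavy_areas, dtype=float)
    ratio = light / heavy
    fit = stats.linregress(d, ratio)
    r2 = float(fit.rvalue**2) if not math.isnan(fit.rvalue) else 0.0

    blank = np.asarray(blank_areas, dtype=float)
    threshold = blank.mean() + 3.0 * blank.std(ddof=1 if len(blank) > 1 else 0)
    # fitted light signal at each level (light vs dilution regression)
    sig_fit = stats.linregress(d, light)
    lod = math.inf
    for dil in sorted(d):
        if sig_fit.slope * dil + sig_fit.intercept > threshold:
            lod = analyte_conc_nm * dil
            break
    usable = r2 >= params.r_squared_threshold and lod <= params.lod_limit_nm
    reason = "" if usable else (
        f"r_squared {r2:.3f} < {params.r_squared_threshold}"
        if r2 < params.r_squared_threshold
        else f"LOD {lod:.3g} nM > {params.lod_limit_nm} nM"
    )
    return CalibrationResult(
        peptide, product_ion, float(fit.slope), float(fit.intercept), r2, lod,
        usable, reason,
    )


# ---------------------------------------------------------------------------
# quantification

def standard_amount_fmol(
    standard_conc_ug_ml: float, qconcat_mw_da: float, digest_volume_ul: float
) -> float:
    """fmol of each (equimolar) signature peptide in the digest aliquot."""
    if qconcat_mw_da <= 0 or digest_volume_ul <= 0:
        raise ValueError("MW and digest volume must be > 0")
    moles = standard_conc_ug_ml * 1e-6 / qconcat_mw_da * digest_volume_ul * 1e-3
    return moles * 1e15


def quantify_peptide(
    measurements: Iterable[PeakMeasurement],
    standard_conc_ug_ml: float,
    qconcat_mw_da: float,
    digest_volume_ul: float,
    min_transitions: int = 2,
    usable_transitions: set[str] | None = None,
) -> float:
    """Endogenous peptide amount (fmol in digest) for one peptide in one
    sample.

    Light and heavy areas are summed over the same (validated) transition
    set; the summed-area ratio scales the known heavy standard amount.
    Only unmodified measurements enter the ratio: the standard is unmodified.
    """
    light: dict[str, float] = {}
    heavy: dict[str, float] = {}
    for m in measurements:
        if m.modification_state not in ("none", ""):
            continue
        if usable_transitions is not None and m.product_ion not in usable_transitions:
            continue
        target = light if m.label_state == "light" else heavy
        target[m.product_ion] = target.get(m.product_ion, 0.0) + m.area
    shared = sorted(set(light) & set(heavy))
    if len(shared) < min_transitions:
        raise ValueError(
            f"only {len(shared)} usable transitions; need >= {min_transitions}"
        )
    heavy_sum = sum(heavy[t] for t in shared)
    if heavy_sum == 0:
        raise ValueError("heavy (standard) area sum is zero")
    ratio = sum(light[t] for t in shared) / heavy_sum
    return ratio * standard_amount_fmol(
        standard_conc_ug_ml, qconcat_mw_da, digest_volume_ul
    )


@dataclass(frozen=True)
class ProteinQuant:
    protein_id: str
    sample_id: str
    copies_per_cell: float
    peptide_values: Mapping[str, float]
    n_peptides: int
    single_peptide_flag: bool = False
    sem: float = math.nan


def protein_copies_per_cell(
    peptide_amounts_fmol: Mapping[str, float],
    meta: SampleMeta,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
    min_peptides: int = 2,
    allow_single: bool = True,
    rollup: str = "mean",
) -> ProteinQuant:
    """Roll peptide amounts up to protein copies per cell.

    copies = amount(mol) x N_A / cells-in-digest, averaged over peptides
    (at least ``min_peptides``; a single-peptide value is reported with a
    flag when ``allow_single``).
    """
    if not peptide_amounts_fmol:
        raise ValueError("no quantified peptides")
    cells = meta.cells_in_digest(constants)
    if cells <= 0:
        raise ValueError("zero cells in digest (check OD and volumes)")
    per_pep = {
        pep: amount * 1e-15 * constants.avogadro / cells
        for pep, amount in peptide_amounts_fmol.items()
    }
    n = len(per_pep)
    if n < min_peptides and not allow_single:
        raise ValueError(f"only {n} peptides; need >= {min_peptides}")
    values = np.array(list(per_pep.values()))
    copies = float(np.median(values)) if rollup == "median" else float(values.mean())
    protein_id = ""
    return ProteinQuant(
        protein_id=protein_id,
        sample_id=meta.sample_id,
        copies_per_cell=copies,
        peptide_values=per_pep,
        n_peptides=n,
        single_peptide_flag=n < min_peptides,
    )


def ptm_fraction(modified_area: float, unmodified_area: float) -> float | None:
    """Occupancy = modified / (modified + unmodified), from light areas only.

    Returns None (missing) when both areas are zero.
    """
    if modified_area < 0 or unmodified_area < 0:
        raise ValueError("areas must be >= 0")
    total = modified_area + unmodified_area
    if total == 0:
        return None
    return modified_area / total


# ---------------------------------------------------------------------------
# report-level convenience

def quantify_report(
    measurements: Sequence[PeakMeasurement],
    metas: Mapping[str, SampleMeta],
    peptide_to_protein: Mapping[str, str],
    peptide_to_standard: Mapping[str, str],
    standard_mw: Mapping[str, float],
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
    min_transitions: int = 2,
    min_peptides: int = 2,
    exclude_peptides: set[str] | None = None,
) -> pd.DataFrame:
    """Quantify every protein in every sample of a transition report.

    Returns a tidy frame: protein, sample_id, strain, time_h, replicate,
    copies_per_cell, n_peptides.  ``exclude_peptides`` removes peptides
    (typically the modifiable PTM-site peptides, which are partially in the
    modified state) from the copy-number rollup.
    """
    exclude_peptides = exclude_peptides or set()
    by_sample_pep: dict[tuple[str, str], list[PeakMeasurement]] = {}
    for m in measurements:
        if m.peptide in exclude_peptides:
            continue
        by_sample_pep.setdefault((m.sample_id, m.peptide), []).append(m)

    rows = []
    by_sample_protein: dict[tuple[str, str], dict[str, float]] = {}
    for (sample_id, pep), ms in by_sample_pep.items():
        if pep not in peptide_to_protein or sample_id not in metas:
            continue
        meta = metas[sample_id]
        std = peptide_to_standard[pep]
        conc = meta.standard_concentrations.get(std)
        if conc is None:
            continue
        try:
            amount = quantify_peptide(
                ms, conc, standard_mw[std], meta.digest_volume_ul, min_transitions
            )
        except ValueError:
            continue
        key = (sample_id, peptide_to_protein[pep])
        by_sample_protein.setdefault(key, {})[pep] = amount

    for (sample_id, protein), amounts in sorted(by_sample_protein.items()):
        meta = metas[sample_id]
        q = protein_copies_per_cell(
            amounts, meta, constants, min_peptides=min_peptides
        )
        rows.append(
            {
                "protein": protein,
                "sample_id": sample_id,
                "strain": meta.strain,
                "time_h": meta.time_h,
                "replicate": meta.replicate,
                "copies_per_cell": q.copies_per_cell,
                "n_peptides": q.n_peptides,
                "single_peptide_flag": q.single_peptide_flag,
            }
        )
    return pd.DataFrame(rows)


def ptm_report(
    measurements: Sequence[PeakMeasurement],
    metas: Mapping[str, SampleMeta],
    peptide_to_protein: Mapping[str, str],
    modifiable_peptides: set[str] | None = None,
) -> pd.DataFrame:
    """Modification occupancy per protein per sample from light areas.

    Only the designated modifiable (site-carrying) peptides enter the
    modified/total ratio; quantotypic peptides are never partially modified
    and would dilute the occupancy estimate.
    """
    sums: dict[tuple[str, str], dict[str, float]] = {}
    for m in measurements:
        if m.label_state != "light" or m.peptide not in peptide_to_protein:
            continue
        if modifiable_peptides is not None and m.peptide not in modifiable_peptides:
            continue
        key = (m.sample_id, peptide_to_protein[m.peptide])
        d = sums.setdefault(key, {"mod": 0.0, "unmod": 0.0})
        if m.modification_state not in ("none", ""):
            d["mod"] += m.area
        else:
            d["unmod"] += m.area
    rows = []
    for (sample_id, protein), d in sorted(sums.items()):
        if d["mod"] == 0 and d["unmod"] == 0:
            continue
        frac = ptm_fraction(d["mod"], d["unmod"])
        meta = metas.get(sample_id)
        rows.append(
            {
                "protein": protein,
                "sample_id": sample_id,
                "strain": meta.strain if meta else "",
                "time_h": meta.time_h if meta else math.nan,
                "replicate": meta.replicate if meta else 1,
                "fraction_modified": frac,
            }
        )
    return pd.DataFrame(rows)


def replicate_summary(quant: pd.DataFrame, value: str = "copies_per_cell") -> pd.DataFrame:
    """Mean +/- SEM across biological replicates per protein/strain/time."""
    g = quant.groupby(["protein", "strain", "time_h"])[value]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": value, "count": "n_replicates"})
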