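"""QconCAT standard design: proteotypic peptide selection, concatamer
assembly, and SRM transition-list generation.

A QconCAT is an artificial concatamer of signature peptides expressed with
heavy-isotope labels and spiked into samples as a stoichiometric internal
standard.  Candidate peptides must be proteotypic (unique in the proteome),
5-25 residues, observable as doubly charged precursors in the instrument
m/z range with a workable y-ion series, and free of His/Met/Cys (oxidation-
and charge-state-prone residues).  Peptides with proline-adjacent or
double-basic (KK/RR) cut sites are excluded where possible: these filters
are soft and are relaxed, in a documented order, when too few candidates
survive.  In the concatamer each signature peptide keeps the three native
residues flanking its tryptic cut sites so that digestion kinetics match
the endogenous protein, and unique BSA peptides cap both termini as
controls against exoproteolysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .constants import HEAVY_SHIFT_KR
from .sequences import (
    Peptide,
    ProteinEntry,
    digest_trypsin,
    ion_mz,
    peptide_mass,
)

# Default BSA control peptides (tryptic peptides of mature bovine serum
# albumin, P02769), used as terminal degradation controls.
DEFAULT_BSA_CONTROLS = ("LVNELTEFAK", "HLVDEPQNLIK")


@dataclass(frozen=True)
class CandidateFilterParams:
    """Filter thresholds for proteotypic candidate selection."""

    min_len: int = 5
    max_len: int = 25
    mz_min: float = 50.0
    mz_max: float = 1800.0
    required_charge: int = 2
    min_y_ions: int = 3          # candidate needs strictly more than this
    forbidden_residues: frozenset[str] = frozenset("HMC")
    exclude_proline_adjacent: bool = True
    exclude_double_basic: bool = True
    equate_il: bool = False      # treat I and L as indistinguishable
    min_candidates: int = 2      # relax soft filters below this count
    uniqueness_missed_cleavages: int = 1

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")


@dataclass(frozen=True)
class CandidateEvaluation:
    """A tryptic peptide annotated with every filter outcome."""

    peptide: Peptide
    hard_failures: tuple[str, ...]
    soft_failures: tuple[str, ...]
    passed: bool

    @property
    def reasons(self) -> tuple[str, ...]:
        return self.hard_failures + self.soft_failures


def _count_y_ions(sequence: str, params: CandidateFilterParams) -> int:
    """Singly charged y1..y(n-1) fragments within the instrument range."""
    return sum(
        1
        for n in range(1, len(sequence))
        if params.mz_min <= ion_mz(sequence, 1, f"y{n}") <= params.mz_max
    )


def proteome_peptide_counts(
    proteome: Sequence[ProteinEntry], params: CandidateFilterParams
) -> dict[str, int]:
    """Occurrence counts of every fully tryptic peptide (m <= uniqueness
    limit) across the proteome, keyed by (optionally I/L-collapsed) sequence."""
    counts: dict[str, int] = {}
    for entry in proteome:
        for pep in digest_trypsin(
            entry.sequence, params.uniqueness_missed_cleavages, entry.id
        ):
            key = pep.sequence.replace("I", "L") if params.equate_il else pep.sequence
            counts[key] = counts.get(key, 0) + 1
    return counts


def select_candidates(
    protein: ProteinEntry,
    proteome: Sequence[ProteinEntry],
    params: CandidateFilterParams | None = None,
    peptide_counts: dict[str, int] | None = None,
) -> list[CandidateEvaluation]:
    """Evaluate every tryptic peptide of ``protein`` against the filters.

    Hard filters (uniqueness, length, precursor m/z, y-ion count, forbidden
    residues) always apply.  Soft filters (double-basic then proline-adjacent
    cut sites) are relaxed in that order if fewer than
    ``params.min_candidates`` peptides survive.
    """
    params = params or CandidateFilterParams()
    if not any(e.id == protein.id for e in proteome):
        raise ValueError(f"protein {protein.id!r} not present in proteome")
    if peptide_counts is None:
        peptide_counts = proteome_peptide_counts(proteome, params)

    seq = protein.sequence
    evaluations: list[CandidateEvaluation] = []
    for pep in digest_trypsin(seq, 0, protein.id):
        hard: list[str] = []
        soft: list[str] = []
        key = pep.sequence.replace("I", "L") if params.equate_il else pep.sequence
        if peptide_counts.get(key, 0) != 1:
            hard.append("not_unique")
        if not params.min_len <= len(pep) <= params.max_len:
            hard.append("length")
        mz = ion_mz(pep.sequence, params.required_charge, "precursor")
        if not params.mz_min <= mz <= params.mz_max:
            hard.append("precursor_mz")
        if _count_y_ions(pep.sequence, params) <= params.min_y_ions:
            hard.append("y_ion_count")
        bad = sorted(params.forbidden_residues & set(pep.sequence))
        if bad:
            hard.append("forbidden_residue:" + "".join(bad))
        # cut-site context in the native protein (0-based indices)
        before = seq[pep.start - 2] if pep.start > 1 else ""
        after = seq[pep.end] if pep.end < len(seq) else ""
        n_term = seq[pep.start - 1]
        c_term = seq[pep.end - 1]
        if params.exclude_proline_adjacent and (n_term == "P" or after == "P"):
            soft.append("proline_adjacent")
        if params.exclude_double_basic and (
            before in "KR" or (c_term in "KR" and after in "KR")
        ):
            soft.append("double_basic")
        evaluations.append(
            CandidateEvaluation(pep, tuple(hard), tuple(soft), not hard and not soft)
        )

    # soft-filter relaxation, documented order: double_basic first, then
    # proline_adjacent
    relaxed: frozenset[str] = frozenset()
    for ignore in (frozenset(), frozenset({"double_basic"}),
                   frozenset({"double_basic", "proline_adjacent"})):
        relaxed = ignore
        n_pass = sum(
            1
            for e in evaluations
            if not e.hard_failures and set(e.soft_failures) <= ignore
        )
        if n_pass >= params.min_candidates:
            break
    return [
        replace(
            e,
            passed=not e.hard_failures and set(e.soft_failures) <= relaxed,
        )
        for e in evaluations
    ]


@dataclass(frozen=True)
class QconCATSegment:
    upstream_flank: str
    peptide: str
    downstream_flank: str

    @property
    def sequence(self) -> str:
        return self.upstream_flank + self.peptide + self.downstream_flank


@dataclass(frozen=True)
class QconCATDesign:
    """An assembled concatamer standard."""

    name: str
    segments: tuple[QconCATSegment, ...]
    bsa_controls: tuple[str, str]
    full_sequence: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        full = (
            self.bsa_controls[0]
            + "".join(s.sequence for s in self.segments)
            + self.bsa_controls[1]
        )
        object.__setattr__(self, "full_sequence", full)

    @property
    def signature_peptides(self) -> tuple[str, ...]:
        return tuple(s.peptide for s in self.segments)

    @property
    def monoisotopic_mass(self) -> float:
        return peptide_mass(self.full_sequence, "light")

    @property
    def heavy_mass(self) -> float:
        return peptide_mass(self.full_sequence, "heavy")


class DesignError(ValueError):
    pass


def native_context(peptide: Peptide, parent: ProteinEntry, n: int = 3) -> tuple[str, str]:
    """Up to ``n`` native residues flanking the peptide's cut sites; empty at
    a protein terminus."""
    if peptide.parent_id != parent.id:
        raise ValueError("peptide does not belong to parent")
    seq = parent.sequence
    up = seq[max(0, peptide.start - 1 - n) : peptide.start - 1]
    down = seq[peptide.end : peptide.end + n]
    return up, down


def assemble_qconcat(
    peptides: Sequence[tuple[str, str, str]] | Sequence[QconCATSegment],
    bsa_controls: tuple[str, str] = DEFAULT_BSA_CONTROLS,
    name: str = "QconCAT",
) -> QconCATDesign:
    """Assemble a concatamer from (upstream_flank, peptide, downstream_flank)
    segments, capped by the two BSA control peptides.

    Raises :class:`DesignError` if any signature peptide would not be released
    intact and exactly once by tryptic digestion of the full sequence.
    """
    if not peptides:
        raise DesignError("empty peptide list")
    segments = tuple(
        s if isinstance(s, QconCATSegment) else QconCATSegment(*s) for s in peptides
    )
    design = QconCATDesign(name=name, segments=segments, bsa_controls=tuple(bsa_controls))
    release = verify_release(design)
    bad = [p for p in design.signature_peptides if not release[p]]
    if bad:
        raise DesignError(
            f"design {name!r}: peptides not released intact exactly once: {bad}"
        )
    return design


def verify_release(design: QconCATDesign) -> dict[str, bool]:
    """Per signature peptide (and BSA control): released intact exactly once
    by a complete tryptic digest of the concatamer?"""
    fragments = [
        p.sequence for p in digest_trypsin(design.full_sequence, 0, design.name)
    ]
    result: dict[str, bool] = {}
    for pep in design.signature_peptides + design.bsa_controls:
        result[pep] = fragments.count(pep) == 1
    return result


@dataclass(frozen=True)
class TransitionRecord:
    """One SRM transition: a precursor -> product ion pair to monitor."""

    protein_id: str
    peptide: str
    precursor_mz: float
    precursor_charge: int
    product_ion: str
    product_mz: float
    label_state: str
    collision_energy: float
    declustering_potential: float
    retention_window_s: float
    dwell_time_ms: float


@dataclass(frozen=True)
class TransitionListParams:
    """Instrument-method parameters for transition-list generation.

    CE/DP are linear functions of precursor m/z; the default coefficients
    are configuration values in the style of vendor defaults for doubly
    charged precursors, not a claim about any particular instrument.
    """

    n_products: int = 3
    precursor_charge: int = 2
    mz_min: float = 50.0
    mz_max: float = 1800.0
    ce_slope: float = 0.044
    ce_intercept: float = 5.5
    dp_slope: float = 0.061
    dp_intercept: float = 50.5
    dwell_time_ms: float = 3.0
    retention_window_s: float = 270.0
    heavy_shift: float = HEAVY_SHIFT_KR


def build_transition_list(
    design: QconCATDesign,
    peptide_protein_map: dict[str, str] | None = None,
    params: TransitionListParams | None = None,
) -> list[TransitionRecord]:
    """Light and heavy transitions for every signature peptide of a design.

    For each peptide: the doubly charged precursor and the ``n_products``
    highest-index singly charged y-ions inside the instrument m/z range.
    """
    params = params or TransitionListParams()
    peptide_protein_map = peptide_protein_map or {}
    records: list[TransitionRecord] = []
    for pep in design.signature_peptides:
        y_in_range = [
            n
            for n in range(1, len(pep))
            if params.mz_min <= ion_mz(pep, 1, f"y{n}") <= params.mz_max
        ]
        if not y_in_range:
            raise DesignError(f"no in-range y-ions for peptide {pep!r}")
        chosen = sorted(y_in_range, reverse=True)[: params.n_products]
        protein_id = peptide_protein_map.get(pep, design.name)
        for label in ("light", "heavy"):
            prec = ion_mz(
                pep, params.precursor_charge, "precursor", label,
                heavy_shift=params.heavy_shift,
            )
            ce = params.ce_slope * prec + params.ce_intercept
            dp = params.dp_slope * prec + params.dp_intercept
            for n in sorted(chosen):
                records.append(
                    TransitionRecord(
                        protein_id=protein_id,
                        peptide=pep,
                        precursor_mz=prec,
                        precursor_charge=params.precursor_charge,
                        product_ion=f"y{n}",
                        product_mz=ion_mz(
                            pep, 1, f"y{n}", label, heavy_shift=params.heavy_shift
                        ),
                        label_state=label,
                        collision_energy=ce,
                        declustering_potential=dp,
                        retention_window_s=params.retention_window_s,
                        dwell_time_ms=params.dwell_time_ms,
                    )
                )
    return records


def transitions_to_frame(records: Iterable[TransitionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": r.protein_id,
                "peptide": r.peptide,
                "precursor_mz": r.precursor_mz,
                "precursor_charge": r.precursor_charge,
                "product_mz": r.product_mz,
                "fragment_ion": r.product_ion,
                "label": r.label_state,
                "collision_energy": r.collision_energy,
                "declustering_potential": r.declustering_potential,
                "retention_window_s": r.retention_window_s,
                "dwell_time_ms": r.dwell_time_ms,
            }
            for r in records
        ]
    )


def write_transition_csv(records: Iterable[TransitionRecord], path: str | Path) -> None:
    transitions_to_frame(records).to_csv(path, index=False)
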