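"""Amino-acid supply/demand resource-allocation model for diazotrophy.

During the transition to nitrogen fixation the cell must synthesise an
enormous quantity of nitrogenase (NifHDK) and accessory Nif protein while
starved of fixed nitrogen.  This module turns measured copy-number time
courses into translation rates, per-amino-acid substrate demand, the time
each finite amino-acid pool could sustain that demand, assembled-complex
counts (limited by the least abundant subunit), the implied N-fixation
rate, and the fraction of proteome mass and ribosome capacity committed to
Nif synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .constants import DEFAULT_CONSTANTS, PhysiologyConstants
from .sequences import ProteinEntry

#: Nitrogenase subunit stoichiometry: two Fe-protein (NifH) homodimers
#: serving one MoFe (NifD2K2) heterotetramer.
NITROGENASE_STOICHIOMETRY: dict[str, int] = {"NifH": 4, "NifD": 2, "NifK": 2}
#: Glutamine synthetase assembles as a dodecamer.
GS_SUBUNITS = 12


@dataclass(frozen=True)
class RateEstimate:
    """Net synthesis rate of one protein over a time window.

    Degradation is not modelled, so negative rates (declining copy number)
    are reported with a flag rather than truncated; demand computed from
    them may be underestimated.
    """

    protein_id: str
    window_h: tuple[float, float]
    rate_per_s: float
    degradation_flag: bool = False


def synthesis_rate(
    times_h: Sequence[float],
    copies: Sequence[float],
    window_h: tuple[float, float] = (7.5, 12.5),
    protein_id: str = "",
) -> RateEstimate:
    """Net production rate (copies cell^-1 s^-1) from the change in copy
    number between the window endpoints."""
    t1, t2 = window_h
    if t2 <= t1:
        raise ValueError("window end must exceed start")
    lookup = dict(zip(times_h, copies))
    for t in (t1, t2):
        if t not in lookup:
            raise ValueError(f"no copy-number observation at t = {t} h")
    rate = (lookup[t2] - lookup[t1]) / ((t2 - t1) * 3600.0)
    return RateEstimate(protein_id, (t1, t2), rate, degradation_flag=rate < 0)


@dataclass(frozen=True)
class DemandProfile:
    """Per-amino-acid substrate consumption, molecules cell^-1 s^-1."""

    per_amino_acid: Mapping[str, float]
    total_per_s: float


def amino_acid_demand(
    rates: Sequence[RateEstimate], proteome: Mapping[str, ProteinEntry]
) -> DemandProfile:
    """Demand for each amino acid implied by a set of synthesis rates.

    demand(a) = sum over proteins of rate_p x (count of residue a in p);
    the total equals sum of rate_p x length_p exactly.
    """
    per_aa: dict[str, float] = {}
    total = 0.0
    for r in rates:
        entry = proteome.get(r.protein_id)
        if entry is None:
            raise KeyError(f"no sequence for protein {r.protein_id!r}")
        for aa, count in entry.residue_counts().items():
            if count:
                per_aa[aa] = per_aa.get(aa, 0.0) + r.rate_per_s * count
        total += r.rate_per_s * entry.length
    return DemandProfile(per_aa, total)


def pool_support_time(pool_molecules: float, demand_per_s: float) -> float:
    """Seconds a finite, unreplenished pool can sustain a demand."""
    if pool_molecules < 0 or demand_per_s < 0:
        raise ValueError("pool and demand must be >= 0")
    if demand_per_s == 0:
        return math.inf
    return pool_molecules / demand_per_s


def complex_count(
    subunit_copies: Mapping[str, float], stoichiometry: Mapping[str, int]
) -> float:
    """Assembled complexes per cell, limited by the least abundant subunit
    relative to its required copy number per complex."""
    counts = []
    for subunit, required in stoichiometry.items():
        if required < 1:
            raise ValueError("stoichiometry counts must be >= 1")
        if subunit not in subunit_copies:
            raise KeyError(f"missing copy number for subunit {subunit!r}")
        counts.append(subunit_copies[subunit] / required)
    if not counts:
        raise ValueError("empty stoichiometry")
    return min(counts)


def round_sig(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (headline-figure convention)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + sig - 1)


def fixation_rate(
    complexes_per_cell: float,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> float:
    """N atoms fixed cell^-1 s^-1 = enzymes x kcat x N atoms per turnover."""
    if complexes_per_cell < 0:
        raise ValueError("complexes must be >= 0")
    return (
        complexes_per_cell
        * constants.nitrogenase_kcat
        * constants.n_atoms_per_turnover
    )


def proteome_fraction(
    copies: Mapping[str, float],
    proteome: Mapping[str, ProteinEntry],
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> tuple[float, bool]:
    """Fraction of all polymerised residues residing in a protein subset.

    Returns (fraction, consistency_warning); the warning is set when the
    subset alone exceeds the assumed total proteome size.
    """
    residues = 0.0
    for pid, n in copies.items():
        if n < 0:
            raise ValueError("copy numbers must be >= 0")
        residues += n * proteome[pid].length
    fraction = residues / constants.total_proteome_aa
    return fraction, fraction > 1.0


def ribosome_occupancy(
    total_demand_per_s: float,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> tuple[float, bool]:
    """Fraction of the active ribosome pool needed to sustain a residue
    incorporation rate; (fraction, over-capacity warning)."""
    if total_demand_per_s < 0:
        raise ValueError("demand must be >= 0")
    capacity = constants.active_ribosomes * constants.elongation_rate
    fraction = total_demand_per_s / capacity
    return fraction, fraction > 1.0


def allocation_summary(
    rates: Sequence[RateEstimate],
    proteome: Mapping[str, ProteinEntry],
    copies_at_end: Mapping[str, float],
    pools_molecules: Mapping[str, float],
    stoichiometry: Mapping[str, int] | None = None,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> dict:
    """End-to-end allocation report for one strain and window.

    Combines synthesis rates, the demand they imply, pool support times at
    that demand, the assembled nitrogenase count at the window end, and the
    derived fixation-rate / proteome-fraction / ribosome-occupancy figures.
    """
    stoichiometry = dict(stoichiometry or NITROGENASE_STOICHIOMETRY)
    demand = amino_acid_demand(rates, proteome)
    support = {
        aa: pool_support_time(pool, demand.per_amino_acid.get(aa, 0.0))
        for aa, pool in pools_molecules.items()
    }
    enzymes = complex_count(copies_at_end, stoichiometry)
    fraction, frac_warn = proteome_fraction(copies_at_end, proteome, constants)
    occupancy, occ_warn = ribosome_occupancy(demand.total_per_s, constants)
    return {
        "window_h": list(rates[0].window_h) if rates else None,
        "total_demand_residues_per_s": demand.total_per_s,
        "demand_per_amino_acid": dict(sorted(demand.per_amino_acid.items())),
        "pool_support_time_s": support,
        "nitrogenase_complexes_per_cell": enzymes,
        "nitrogenase_complexes_2sf": round_sig(enzymes),
        "n_fixation_rate_atoms_per_s": fixation_rate(enzymes, constants),
        "proteome_fraction": fraction,
        "proteome_fraction_warning": frac_warn,
        "ribosome_occupancy": occupancy,
        "ribosome_occupancy_warning": occ_warn,
    }
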