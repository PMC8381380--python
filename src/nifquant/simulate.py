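"""Synthetic ground-truth scenarios for the diazotrophy-transition workflow.

The generator emulates the statistical structure of an ammonium run-out
experiment in a free-living diazotroph: exponential growth on a limiting
NH4+ supply, growth arrest at starvation, delayed induction of the nif
regulon (structural nitrogenase subunits accumulating faster than the
accessory proteins), PII-protein uridylylation tracking N status,
amino-acid pools that mostly shrink but partly accumulate under
starvation, and the headspace gas, OD and colorimetric-assay channels
through which all of this is observed.  Kinetics are phenomenological
(logistic induction, first-order pool relaxation) rather than mechanistic:
the generator's job is to provide known ground truth with realistic noise,
not to model the ntr cascade.

Three strains are produced: a wild type that fixes nitrogen and resumes
slow growth; a regulatory deletion ("delta_nifLA") with no nif expression
at all; and a truncation mutant ("nifK_trunc") that expresses nif protein
(at reduced level, lacking the positive feedback from fixed N) but has no
nitrogenase activity.

The noiseless skeleton (proteome, kinetics, response factors) is fixed and
independent of the user seed; the seed drives measurement noise only, so
distinct seeds share identical underlying truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import NITROGENASE_STOICHIOMETRY, complex_count
from .constants import DEFAULT_CONSTANTS, PhysiologyConstants
from .design import (
    CandidateFilterParams,
    QconCATDesign,
    assemble_qconcat,
    native_context,
    proteome_peptide_counts,
    select_candidates,
)
from .physiology import NH4Curve
from .sequences import Peptide, ProteinEntry, digest_trypsin
from .srm import SampleMeta

WILD_TYPE = "wild_type"
DELTA_NIFLA = "delta_nifLA"
NIFK_TRUNC = "nifK_trunc"
STRAINS = (WILD_TYPE, DELTA_NIFLA, NIFK_TRUNC)

# Internal seed for the noiseless skeleton (proteome, response factors);
# deliberately decoupled from the user-facing noise seed.
_SKELETON_SEED = 20177

# amino-acid composition weights for random protein sequences (roughly
# enterobacterial usage, with rare H/M/C/W kept rare)
_AA_WEIGHTS = {
    "A": 0.090, "C": 0.005, "D": 0.050, "E": 0.060, "F": 0.040,
    "G": 0.080, "H": 0.015, "I": 0.050, "K": 0.055, "L": 0.090,
    "M": 0.015, "N": 0.040, "P": 0.040, "Q": 0.040, "R": 0.055,
    "S": 0.060, "T": 0.055, "V": 0.070, "W": 0.010, "Y": 0.030,
}

# Tyr-containing tryptic peptides embedded into the PII proteins so each
# has a defined uridylylatable signature peptide.
MODIFIABLE_PEPTIDES = {"GlnB": "SEYSVDLITGK", "GlnK": "TAEYGVNLIFK"}


def _logistic(t: float, t_mid: float, tau: float) -> float:
    return 1.0 / (1.0 + math.exp(-(t - t_mid) / tau))


@dataclass(frozen=True)
class ProteinKinetics:
    """Logistic copy-number trajectory: baseline + amplitude * f(t)."""

    length: int
    baseline: float
    amplitude: float
    t_mid_h: float
    tau_h: float
    regulon: str          # nif_structural | nif_accessory | ntr | background

    def copies(self, t_h: float) -> float:
        if self.tau_h <= 0:
            return self.baseline + self.amplitude
        return self.baseline + self.amplitude * _logistic(t_h, self.t_mid_h, self.tau_h)


#: Default target-protein kinetics.  Structural nitrogenase subunits rise
#: late but steeply (NifK limiting at 2 copies per complex; NifH kept near
#: twice the NifDK level); accessory Nif proteins induce slightly earlier
#: but saturate lower; ntr proteins respond during run-out itself.
TARGET_KINETICS: dict[str, ProteinKinetics] = {
    "NifH": ProteinKinetics(290, 0.0, 228_000, 9.2, 1.0, "nif_structural"),
    "NifD": ProteinKinetics(480, 0.0, 114_000, 9.2, 1.0, "nif_structural"),
    "NifK": ProteinKinetics(520, 0.0, 103_700, 9.2, 1.0, "nif_structural"),
    "NifB": ProteinKinetics(470, 0.0, 9_000, 8.5, 1.5, "nif_accessory"),
    "NifE": ProteinKinetics(455, 0.0, 7_000, 8.5, 1.5, "nif_accessory"),
    "NifN": ProteinKinetics(410, 0.0, 6_000, 8.5, 1.5, "nif_accessory"),
    "NifA": ProteinKinetics(522, 0.0, 2_500, 8.5, 1.5, "nif_accessory"),
    "GlnB": ProteinKinetics(112, 350.0, 0.0, 0.0, -1.0, "ntr"),
    "GlnK": ProteinKinetics(112, 200.0, 8_000, 3.0, 0.8, "ntr"),
    "GS": ProteinKinetics(469, 5_500, 11_500, 1.2, 0.5, "ntr"),
}

# PII uridylylation as a Hill function of NH4+: (replete level, starved level)
PTM_PARAMS = {
    "GlnK": (0.35, 0.97),
    "GlnB": (0.05, 0.75),
}
PTM_NH4_K_UM = 120.0
PTM_NH4_HILL = 2.0

# amino-acid pool model: replete intracellular molarity and behaviour class
# ("decline" with a floor fraction, "accumulate" with a gain, or "stable")
AA_POOL_MODEL: dict[str, tuple[float, str, float]] = {
    "E": (7.0e-2, "decline", 0.20),   # glutamate: ~5-fold drop
    "Q": (4.0e-3, "decline", 0.04),   # glutamine: >25-fold drop
    "N": (1.0e-3, "decline", 0.08),
    "D": (2.0e-3, "decline", 0.08),
    "I": (4.0e-4, "decline", 0.08),
    "V": (1.0e-3, "decline", 0.08),
    "A": (5.0e-3, "decline", 0.30),
    "G": (2.0e-3, "decline", 0.15),
    "S": (1.0e-3, "decline", 0.15),
    "T": (8.0e-4, "decline", 0.15),
    "L": (8.0e-4, "decline", 0.15),
    "F": (3.0e-4, "decline", 0.15),
    "H": (2.0e-4, "decline", 0.025),  # histidine: down to ~5 uM
    "W": (1.0e-4, "stable", 0.0),
    "M": (2.0e-4, "stable", 0.0),
    "C": (1.0e-4, "stable", 0.0),
    "P": (2.0e-3, "accumulate", 1.5),
    "R": (1.0e-3, "accumulate", 1.5),
    "K": (8.0e-4, "accumulate", 1.5),
    "Y": (3.0e-4, "accumulate", 1.5),
}
# extra late accumulation in the non-fixing strains (fold at 12.5 h)
AA_NONFIXER_EXTRA = {"P": 9.0, "K": 4.0, "R": 1.5, "Y": 1.5}


@dataclass(frozen=True)
class ScenarioParams:
    """Study conditions for one synthetic run-out experiment."""

    seed: int = 0
    n_background_proteins: int = 12
    background_length_range: tuple[int, int] = (150, 450)
    initial_nh4_um: float = 500.0          # 0.5 mM NH4Cl
    od0: float = 0.1
    pre_growth_rate_per_h: float = 0.25
    starvation_threshold_um: float = 10.0
    nh4_yield_um_per_od: float = 2000.0    # NH4 consumed per unit OD formed
    diazotrophic_mu_max_per_h: float = 0.12
    diazotrophic_k_enzymes: float = 8000.0
    nif_feedback_factor: float = 0.1       # nif level without fixed-N feedback
    sampling_times_h: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0, 12.5)
    timestep_h: float = 0.01
    replicates: int = 3
    noise_cv_area: float = 0.05
    noise_od_sd: float = 0.002
    noise_abs_sd: float = 0.002
    culture_volume_ml: float = 15.0
    resuspension_volume_ul: float = 500.0
    aliquot_volume_ul: float = 30.0
    digest_volume_ul: float = 300.0
    extract_volume_ul: float = 100.0
    derivatisation_dilution: float = 10.0
    ethylene_nmol_per_enzyme_h: float = 1e-4 * 30
    gc_sampling_dilution: float = 0.95     # headspace loss per sampling event
    gc_nmol_per_area: float = 0.02
    gc_acetylene_area0: float = 1000.0
    calibration_dilutions: tuple[float, ...] = (1.0, 1e-1, 1e-2, 1e-3, 1e-4, 1e-5)
    calibration_baseline_area: float = 5.0
    calibration_baseline_sd: float = 1.5
    standard_concentrations: Mapping[str, float] = field(
        default_factory=lambda: {"QNif1": 0.7, "QNif2": 0.124, "QNtr": 0.97}
    )

    def __post_init__(self) -> None:
        if self.od0 <= 0 or self.initial_nh4_um < 0:
            raise ValueError("non-physical initial conditions")
        if self.timestep_h <= 0 or self.replicates < 1:
            raise ValueError("non-physical simulation parameters")


# ---------------------------------------------------------------------------
# proteome

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = list(_AA_WEIGHTS)
    w = np.array([_AA_WEIGHTS[a] for a in aas])
    return "".join(rng.choice(aas, size=length, p=w / w.sum()))


def make_proteome(params: ScenarioParams) -> list[ProteinEntry]:
    """Synthetic proteome: target proteins plus background.

    Sequences are random draws from a fixed composition (fixed internal
    seed, independent of the noise seed).  The PII proteins carry an
    embedded Tyr-containing tryptic peptide as the uridylylation-site
    surrogate.
    """
    rng = np.random.default_rng(_SKELETON_SEED)
    entries: list[ProteinEntry] = []
    for name, kin in TARGET_KINETICS.items():
        if name in MODIFIABLE_PEPTIDES:
            tag = MODIFIABLE_PEPTIDES[name]
            head_len = max(10, (kin.length - len(tag)) // 2)
            tail_len = kin.length - len(tag) - head_len - 1
            head = _random_sequence(rng, head_len - 1) + "K"
            tail = _random_sequence(rng, tail_len)
            if tail.startswith("P"):
                tail = "A" + tail[1:]
            seq = head + tag + tail
        else:
            seq = _random_sequence(rng, kin.length)
        entries.append(ProteinEntry(id=name, sequence=seq))
    lo, hi = params.background_length_range
    for i in range(params.n_background_proteins):
        entries.append(
            ProteinEntry(
                id=f"BG{i:03d}",
                sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# ground truth

@dataclass(frozen=True)
class GroundTruth:
    """Noiseless per-strain, per-time truth tables."""

    params: ScenarioParams
    proteome: tuple[ProteinEntry, ...]
    times_h: tuple[float, ...]
    od: pd.DataFrame                  # strain, time_h, od600
    nh4_um: pd.DataFrame              # strain, time_h, nh4_um
    protein_copies: pd.DataFrame      # strain, time_h, protein, copies
    ptm_fractions: pd.DataFrame       # strain, time_h, protein, fraction
    aa_pools: pd.DataFrame            # strain, time_h, amino_acid, concentration_m
    enzymes: pd.DataFrame             # strain, time_h, complexes (assembled, active)
    ethylene: pd.DataFrame            # strain, time_h, cumulative_nmol

    def copies_lookup(self, strain: str) -> pd.DataFrame:
        sub = self.protein_copies[self.protein_copies["strain"] == strain]
        return sub.pivot(index="time_h", columns="protein", values="copies")

    def od_lookup(self, strain: str) -> dict[float, float]:
        sub = self.od[self.od["strain"] == strain]
        return dict(zip(sub["time_h"], sub["od600"]))


def _nif_scale(strain: str, params: ScenarioParams) -> float:
    if strain == DELTA_NIFLA:
        return 0.0
    if strain == NIFK_TRUNC:
        return params.nif_feedback_factor
    return 1.0


def _protein_copies(strain: str, t: float, name: str, params: ScenarioParams) -> float:
    kin = TARGET_KINETICS[name]
    if kin.regulon.startswith("nif"):
        return _nif_scale(strain, params) * kin.copies(t)
    return kin.copies(t)


def _active_enzymes(strain: str, t: float, params: ScenarioParams) -> float:
    if strain != WILD_TYPE:
        return 0.0
    copies = {s: _protein_copies(strain, t, s, params) for s in ("NifH", "NifD", "NifK")}
    return complex_count(copies, NITROGENASE_STOICHIOMETRY)


def _assembled_enzymes(strain: str, t: float, params: ScenarioParams) -> float:
    copies = {s: _protein_copies(strain, t, s, params) for s in ("NifH", "NifD", "NifK")}
    return complex_count(copies, NITROGENASE_STOICHIOMETRY)


def _aa_concentration(aa: str, strain: str, t: float) -> float:
    replete, cls, p = AA_POOL_MODEL[aa]
    if cls == "decline":
        floor = replete * p
        return floor + (replete - floor) * (1.0 - _logistic(t, 3.5, 0.8))
    if cls == "accumulate":
        conc = replete * (1.0 + p * _logistic(t, 5.5, 1.0))
        if strain in (DELTA_NIFLA, NIFK_TRUNC):
            extra = AA_NONFIXER_EXTRA.get(aa, 1.0)
            conc *= 1.0 + (extra - 1.0) * _logistic(t, 10.0, 1.0)
        return conc
    return replete


def simulate_timecourse(params: ScenarioParams | None = None) -> GroundTruth:
    """Integrate the culture model and tabulate truth at the sampling times.

    Growth consumes NH4+ at a fixed yield until the starvation threshold,
    then arrests; in the wild type, growth resumes at a rate saturating in
    the active nitrogenase count.  Ethylene (the acetylene-reduction proxy)
    accumulates in proportion to the active enzyme count.
    """
    params = params or ScenarioParams()
    proteome = tuple(make_proteome(params))
    dt = params.timestep_h
    t_end = max(params.sampling_times_h)
    n_steps = int(round(t_end / dt)) + 1

    od_rows, nh4_rows, eth_rows = [], [], []
    copies_rows, ptm_rows, aa_rows, enz_rows = [], [], [], []
    sample_set = set(params.sampling_times_h)

    for strain in STRAINS:
        od = params.od0
        nh4 = params.initial_nh4_um
        ethylene = 0.0
        for step in range(n_steps):
            t = round(step * dt, 9)
            if any(abs(t - s) < dt / 2 for s in sample_set):
                t_s = min(sample_set, key=lambda s: abs(s - t))
                od_rows.append({"strain": strain, "time_h": t_s, "od600": od})
                nh4_rows.append({"strain": strain, "time_h": t_s, "nh4_um": nh4})
                eth_rows.append(
                    {"strain": strain, "time_h": t_s, "cumulative_nmol": ethylene}
                )
                for name in TARGET_KINETICS:
                    copies_rows.append(
                        {
                            "strain": strain,
                            "time_h": t_s,
                            "protein": name,
                            "copies": _protein_copies(strain, t_s, name, params),
                        }
                    )
                for name, (lo_f, hi_f) in PTM_PARAMS.items():
                    x = (nh4 / PTM_NH4_K_UM) ** PTM_NH4_HILL
                    frac = hi_f - (hi_f - lo_f) * x / (1.0 + x)
                    ptm_rows.append(
                        {
                            "strain": strain,
                            "time_h": t_s,
                            "protein": name,
                            "fraction": frac,
                        }
                    )
                for aa in AA_POOL_MODEL:
                    aa_rows.append(
                        {
                            "strain": strain,
                            "time_h": t_s,
                            "amino_acid": aa,
                            "concentration_m": _aa_concentration(aa, strain, t_s),
                        }
                    )
                enz_rows.append(
                    {
                        "strain": strain,
                        "time_h": t_s,
                        "assembled": _assembled_enzymes(strain, t_s, params),
                        "active": _active_enzymes(strain, t_s, params),
                    }
                )
            # dynamics
            enzymes = _active_enzymes(strain, t, params)
            if nh4 > params.starvation_threshold_um:
                mu = params.pre_growth_rate_per_h
            else:
                mu = params.diazotrophic_mu_max_per_h * enzymes / (
                    enzymes + params.diazotrophic_k_enzymes
                )
            d_od = mu * od * dt
            consumed = d_od * params.nh4_yield_um_per_od
            if nh4 > params.starvation_threshold_um:
                nh4 = max(0.0, nh4 - consumed)
            od += d_od
            ethylene += enzymes * params.ethylene_nmol_per_enzyme_h * dt

    return GroundTruth(
        params=params,
        proteome=proteome,
        times_h=tuple(params.sampling_times_h),
        od=pd.DataFrame(od_rows),
        nh4_um=pd.DataFrame(nh4_rows),
        protein_copies=pd.DataFrame(copies_rows),
        ptm_fractions=pd.DataFrame(ptm_rows),
        aa_pools=pd.DataFrame(aa_rows),
        enzymes=pd.DataFrame(enz_rows),
        ethylene=pd.DataFrame(eth_rows),
    )


# ---------------------------------------------------------------------------
# standards design over the synthetic proteome

@dataclass(frozen=True)
class StandardsBundle:
    """QconCAT designs plus the lookup tables the quantification stage needs."""

    designs: Mapping[str, QconCATDesign]
    peptide_to_protein: Mapping[str, str]
    peptide_to_standard: Mapping[str, str]
    standard_mw: Mapping[str, float]
    modifiable_peptides: Mapping[str, str]   # protein -> peptide sequence
    transitions: Mapping[str, tuple[str, ...]]  # peptide -> product ions


_STANDARD_GROUPS = {
    "QNif1": ("NifH", "NifD", "NifK"),
    "QNif2": ("NifB", "NifE", "NifN", "NifA"),
    "QNtr": ("GlnB", "GlnK", "GS"),
}


def design_standards(
    proteome: Sequence[ProteinEntry],
    n_peptides: int = 2,
    filter_params: CandidateFilterParams | None = None,
) -> StandardsBundle:
    """Select signature peptides for every target protein and assemble the
    QconCAT standards (one per target group), with native 3-residue flanks
    and BSA terminal controls."""
    filter_params = filter_params or CandidateFilterParams()
    by_id = {e.id: e for e in proteome}
    counts = proteome_peptide_counts(list(proteome), filter_params)

    peptide_to_protein: dict[str, str] = {}
    peptide_to_standard: dict[str, str] = {}
    modifiable: dict[str, str] = {}
    designs: dict[str, QconCATDesign] = {}
    transitions: dict[str, tuple[str, ...]] = {}

    for std_name, proteins in _STANDARD_GROUPS.items():
        segments = []
        for pid in proteins:
            entry = by_id[pid]
            evals = select_candidates(entry, list(proteome), filter_params, counts)
            chosen: list[Peptide] = []
            seq = entry.sequence
            for ev in evals:
                pep = ev.peptide
                internal = (
                    pep.start > 1 and pep.end < len(seq) and pep.sequence[-1] in "KR"
                )
                taken = pep.sequence in peptide_to_protein
                is_mod_tag = pep.sequence == MODIFIABLE_PEPTIDES.get(pid)
                if ev.passed and internal and not taken and not is_mod_tag:
                    chosen.append(pep)
                if len(chosen) == n_peptides:
                    break
            if len(chosen) < n_peptides:
                raise ValueError(f"not enough signature peptides for {pid!r}")
            if pid in MODIFIABLE_PEPTIDES:
                tag = MODIFIABLE_PEPTIDES[pid]
                for pep in digest_trypsin(seq, 0, pid):
                    if pep.sequence == tag:
                        chosen.append(pep)
                        modifiable[pid] = tag
                        break
            for pep in chosen:
                up, down = native_context(pep, entry)
                segments.append((up, pep.sequence, down))
                peptide_to_protein[pep.sequence] = pid
                peptide_to_standard[pep.sequence] = std_name
        designs[std_name] = assemble_qconcat(segments, name=std_name)

    for pep in peptide_to_protein:
        n = len(pep)
        transitions[pep] = tuple(f"y{k}" for k in range(max(1, n - 3), n))

    return StandardsBundle(
        designs=designs,
        peptide_to_protein=peptide_to_protein,
        peptide_to_standard=peptide_to_standard,
        standard_mw={name: d.heavy_mass for name, d in designs.items()},
        modifiable_peptides=modifiable,
        transitions=transitions,
    )


# ---------------------------------------------------------------------------
# SRM measurement simulation

def _response_factors(bundle: StandardsBundle) -> dict[tuple[str, str], float]:
    """Per-transition ionisation response, fixed by the skeleton seed."""
    rng = np.random.default_rng(_SKELETON_SEED + 1)
    factors: dict[tuple[str, str], float] = {}
    for pep in sorted(bundle.peptide_to_protein):
        for ion in bundle.transitions[pep]:
            factors[(pep, ion)] = float(rng.lognormal(mean=0.0, sigma=0.3))
    return factors


def _sample_id(strain: str, t: float, rep: int) -> str:
    return f"{strain}_t{t:g}_r{rep}"


def build_sample_metas(
    truth: GroundTruth, params: ScenarioParams | None = None
) -> dict[str, SampleMeta]:
    params = params or truth.params
    metas: dict[str, SampleMeta] = {}
    for strain in STRAINS:
        od_at = truth.od_lookup(strain)
        for t in truth.times_h:
            for rep in range(1, params.replicates + 1):
                sid = _sample_id(strain, t, rep)
                metas[sid] = SampleMeta(
                    sample_id=sid,
                    strain=strain,
                    time_h=t,
                    od600=od_at[t],
                    replicate=rep,
                    culture_volume_ml=params.culture_volume_ml,
                    resuspension_volume_ul=params.resuspension_volume_ul,
                    aliquot_volume_ul=params.aliquot_volume_ul,
                    digest_volume_ul=params.digest_volume_ul,
                    standard_concentrations=dict(params.standard_concentrations),
                )
    return metas


def simulate_srm_report(
    truth: GroundTruth,
    bundle: StandardsBundle,
    params: ScenarioParams | None = None,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, dict[str, SampleMeta], pd.DataFrame]:
    """Transition-level peak areas for every strain/time/replicate, plus a
    calibration dilution series.

    Heavy areas are the spiked standard amount times a per-transition
    response factor; light areas are the copy-number-derived endogenous
    amount times the same factor, with multiplicative lognormal noise.
    The modifiable peptide of each PII protein is split into modified and
    unmodified species by the true occupancy.
    """
    params = params or truth.params
    rng = np.random.default_rng(params.seed)
    factors = _response_factors(bundle)
    metas = build_sample_metas(truth, params)
    sigma = (
        math.sqrt(math.log(1.0 + params.noise_cv_area**2))
        if params.noise_cv_area > 0
        else 0.0
    )

    def noisy(x: float) -> float:
        if sigma == 0.0 or x == 0.0:
            return x
        return x * float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    copies_of = {
        strain: truth.copies_lookup(strain) for strain in STRAINS
    }
    ptm_of = {
        (r["strain"], r["time_h"], r["protein"]): r["fraction"]
        for _, r in truth.ptm_fractions.iterrows()
    }
    mod_pep_to_protein = {v: k for k, v in bundle.modifiable_peptides.items()}

    rows = []
    for sid, meta in metas.items():
        cells = meta.cells_in_digest(constants)
        for pep, protein in bundle.peptide_to_protein.items():
            std = bundle.peptide_to_standard[pep]
            heavy_fmol = (
                meta.standard_concentrations[std]
                * 1e-6
                / bundle.standard_mw[std]
                * meta.digest_volume_ul
                * 1e-3
                * 1e15
            )
            copies = float(copies_of[meta.strain].loc[meta.time_h, protein])
            light_fmol = copies * cells / constants.avogadro * 1e15
            frac_mod = 0.0
            if pep in mod_pep_to_protein:
                frac_mod = ptm_of[(meta.strain, meta.time_h, protein)]
            for ion in bundle.transitions[pep]:
                r = factors[(pep, ion)]
                rows.append(
                    {
                        "sample_id": sid,
                        "peptide": pep,
                        "product_ion": ion,
                        "label_state": "heavy",
                        "modification_state": "none",
                        "area": noisy(heavy_fmol * r),
                    }
                )
                if frac_mod > 0.0:
                    rows.append(
                        {
                            "sample_id": sid,
                            "peptide": pep,
                            "product_ion": ion,
                            "label_state": "light",
                            "modification_state": "+UMP",
                            "area": noisy(light_fmol * frac_mod * r),
                        }
                    )
                rows.append(
                    {
                        "sample_id": sid,
                        "peptide": pep,
                        "product_ion": ion,
                        "label_state": "light",
                        "modification_state": "none",
                        "area": noisy(light_fmol * (1.0 - frac_mod) * r),
                    }
                )
    report = pd.DataFrame(rows)

    # calibration: a diazotrophic reference extract titrated against the
    # constant standard, 10^0..10^-5 plus zero-extract blanks
    ref_meta = metas[_sample_id(WILD_TYPE, truth.times_h[-2], 1)]
    cells_ref = ref_meta.cells_in_digest(constants)
    cal_rows = []
    n_blanks = 5
    for pep, protein in bundle.peptide_to_protein.items():
        std = bundle.peptide_to_standard[pep]
        heavy_fmol = (
            ref_meta.standard_concentrations[std]
            * 1e-6
            / bundle.standard_mw[std]
            * ref_meta.digest_volume_ul
            * 1e-3
            * 1e15
        )
        copies = float(copies_of[WILD_TYPE].loc[ref_meta.time_h, protein])
        light_fmol = copies * cells_ref / constants.avogadro * 1e15
        conc_nm = light_fmol * 1e-15 / (ref_meta.digest_volume_ul * 1e-6) * 1e9
        for ion in bundle.transitions[pep]:
            r = factors[(pep, ion)]
            for d in params.calibration_dilutions:
                base = float(
                    rng.normal(
                        params.calibration_baseline_area,
                        params.calibration_baseline_sd,
                    )
                )
                cal_rows.append(
                    {
                        "peptide": pep,
                        "product_ion": ion,
                        "dilution": d,
                        "light_area": noisy(light_fmol * d * r) + max(base, 0.0),
                        "heavy_area": noisy(heavy_fmol * r),
                        "analyte_conc_nm": conc_nm,
                    }
                )
            for _ in range(n_blanks):
                base = float(
                    rng.normal(
                        params.calibration_baseline_area,
                        params.calibration_baseline_sd,
                    )
                )
                cal_rows.append(
                    {
                        "peptide": pep,
                        "product_ion": ion,
                        "dilution": 0.0,
                        "light_area": max(base, 0.0),
                        "heavy_area": noisy(heavy_fmol * r),
                        "analyte_conc_nm": conc_nm,
                    }
                )
    return report, metas, pd.DataFrame(cal_rows)


# ---------------------------------------------------------------------------
# physiology channels

DEFAULT_NH4_ASSAY_CURVE = NH4Curve(
    slope=1.8e-4, intercept=0.04, conc_min_um=78.0, conc_max_um=5000.0
)


def simulate_physiology(
    truth: GroundTruth,
    params: ScenarioParams | None = None,
    assay_curve: NH4Curve = DEFAULT_NH4_ASSAY_CURVE,
) -> pd.DataFrame:
    """OD600, NH4+ assay absorbance and GC peak areas per strain and time.

    Both headspace gases are diluted by a fixed factor at every sampling
    event, so the acetylene-based dilution correction path is exercised.
    """
    params = params or truth.params
    rng = np.random.default_rng(params.seed + 1)
    rows = []
    for strain in STRAINS:
        od_at = truth.od_lookup(strain)
        nh4_at = dict(
            zip(
                truth.nh4_um[truth.nh4_um["strain"] == strain]["time_h"],
                truth.nh4_um[truth.nh4_um["strain"] == strain]["nh4_um"],
            )
        )
        eth_at = dict(
            zip(
                truth.ethylene[truth.ethylene["strain"] == strain]["time_h"],
                truth.ethylene[truth.ethylene["strain"] == strain]["cumulative_nmol"],
            )
        )
        for i, t in enumerate(truth.times_h):
            dilution = params.gc_sampling_dilution**i
            abs690 = (
                assay_curve.slope * nh4_at[t]
                + assay_curve.intercept
                + float(rng.normal(0.0, params.noise_abs_sd))
            )
            rows.append(
                {
                    "strain": strain,
                    "time_h": t,
                    "od600": od_at[t] + float(rng.normal(0.0, params.noise_od_sd)),
                    "nh4_abs690": abs690,
                    "acetylene_area": params.gc_acetylene_area0 * dilution,
                    "ethylene_area": eth_at[t] / params.gc_nmol_per_area * dilution,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# amino-acid measurement simulation

#: per-analyte instrument response (area per uM); fixed skeleton property
def _aa_response_slopes() -> dict[str, float]:
    rng = np.random.default_rng(_SKELETON_SEED + 2)
    return {
        aa: float(rng.uniform(800.0, 1500.0)) for aa in sorted(AA_POOL_MODEL)
    }


#: analytes whose signal droops below 2 uM (quadratic roll-off)
NONLINEAR_LOW_ANALYTES = ("N", "D", "Q")
NONLINEAR_KNEE_UM = 2.0


def _aa_area(aa: str, conc_um: float, slope: float) -> float:
    if aa in NONLINEAR_LOW_ANALYTES and conc_um < NONLINEAR_KNEE_UM:
        return slope * conc_um * (conc_um / NONLINEAR_KNEE_UM)
    return slope * conc_um


def simulate_amino_acid_reports(
    truth: GroundTruth,
    params: ScenarioParams | None = None,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
    standard_levels_um: Sequence[float] = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0, 100.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample peak areas plus external standard-curve tables.

    Returns (sample_areas, standards): sample areas carry strain / time /
    replicate metadata; standards are (analyte, concentration_um, area)
    dilution series, linear except for Asn/Asp/Gln below 2 uM.
    """
    params = params or truth.params
    rng = np.random.default_rng(params.seed + 2)
    slopes = _aa_response_slopes()
    sigma = (
        math.sqrt(math.log(1.0 + params.noise_cv_area**2))
        if params.noise_cv_area > 0
        else 0.0
    )

    def noisy(x: float) -> float:
        if sigma == 0.0 or x == 0.0:
            return x
        return x * float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    std_rows = [
        {
            "analyte": aa,
            "concentration_um": lvl,
            "area": _aa_area(aa, lvl, slopes[aa]),
        }
        for aa in sorted(AA_POOL_MODEL)
        for lvl in standard_levels_um
    ]

    rows = []
    for strain in STRAINS:
        od_at = truth.od_lookup(strain)
        pools = truth.aa_pools[truth.aa_pools["strain"] == strain]
        for t in truth.times_h:
            cells = od_at[t] * params.culture_volume_ml * constants.cells_per_od_ml
            sub = pools[pools["time_h"] == t]
            for rep in range(1, params.replicates + 1):
                sid = _sample_id(strain, t, rep)
                for _, r in sub.iterrows():
                    moles = (
                        r["concentration_m"] * constants.cell_volume_l * cells
                    )
                    conc_extract_um = moles / (params.extract_volume_ul * 1e-6) * 1e6
                    conc_injected = conc_extract_um / params.derivatisation_dilution
                    rows.append(
                        {
                            "sample_id": sid,
                            "strain": strain,
                            "time_h": t,
                            "replicate": rep,
                            "analyte": r["amino_acid"],
                            "area": noisy(
                                _aa_area(r["amino_acid"], conc_injected,
                                         slopes[r["amino_acid"]])
                            ),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(std_rows)


def metabolite_sample_metas(
    truth: GroundTruth, params: ScenarioParams | None = None
):
    """MetaboliteSampleMeta records matching simulate_amino_acid_reports."""
    from .metabolites import MetaboliteSampleMeta

    params = params or truth.params
    metas = {}
    for strain in STRAINS:
        od_at = truth.od_lookup(strain)
        for t in truth.times_h:
            for rep in range(1, params.replicates + 1):
                sid = _sample_id(strain, t, rep)
                metas[sid] = MetaboliteSampleMeta(
                    sample_id=sid,
                    strain=strain,
                    time_h=t,
                    od600=od_at[t],
                    replicate=rep,
                    culture_volume_ml=params.culture_volume_ml,
                    extract_volume_ul=params.extract_volume_ul,
                    derivatisation_dilution=params.derivatisation_dilution,
                )
    return metas
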