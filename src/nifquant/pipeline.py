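"""End-to-end orchestration: simulate -> design -> quantify -> metabolites
-> physiology -> allocate, with reproducible, provenance-stamped outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .allocation import (
    NITROGENASE_STOICHIOMETRY,
    allocation_summary,
    synthesis_rate,
)
from .constants import DEFAULT_CONSTANTS, PhysiologyConstants
from .metabolites import (
    base_mean_fold_changes,
    fit_calibration,
    pools_to_frame,
    quantify_amino_acids,
    strain_contrast,
)
from .physiology import acetylene_reduction_rate, growth_rate
from .simulate import (
    DELTA_NIFLA,
    NIFK_TRUNC,
    STRAINS,
    WILD_TYPE,
    GroundTruth,
    ScenarioParams,
    design_standards,
    metabolite_sample_metas,
    simulate_amino_acid_reports,
    simulate_physiology,
    simulate_srm_report,
    simulate_timecourse,
)
from .srm import parse_report, ptm_report, quantify_report, replicate_summary

log = logging.getLogger("nifquant")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    seed: int = 0
    outdir: Path = Path("nifquant_run")
    window_h: tuple[float, float] = (7.5, 12.5)
    scenario_overrides: Mapping[str, Any] = field(default_factory=dict)
    constants_overrides: Mapping[str, float] = field(default_factory=dict)

    def scenario(self) -> ScenarioParams:
        return ScenarioParams(seed=self.seed, **dict(self.scenario_overrides))

    def constants(self) -> PhysiologyConstants:
        if not self.constants_overrides:
            return DEFAULT_CONSTANTS
        return PhysiologyConstants(**dict(self.constants_overrides))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        if "window_h" in raw:
            raw["window_h"] = tuple(raw["window_h"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": str(self.outdir),
            "window_h": list(self.window_h),
            "scenario_overrides": dict(self.scenario_overrides),
            "constants_overrides": dict(self.constants_overrides),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# nifquant {__version__} seed={config.seed} "
        f"config={config.config_hash()}\n"
        "# peptide coordinates 1-based inclusive; motif positions 0-based half-open\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute every stage in dependency order and return the results.

    Outputs (when ``write_outputs``): quant/PTM/pool TSV tables, a
    calibration summary, rate tables, and an allocation summary JSON per
    strain, all carrying version/seed/config-hash provenance headers.
    """
    constants = config.constants()
    params = config.scenario()
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    log.info("simulating ground truth")
    truth: GroundTruth = simulate_timecourse(params)
    proteome = {e.id: e for e in truth.proteome}

    log.info("designing QconCAT standards")
    bundle = design_standards(truth.proteome)

    log.info("simulating and quantifying SRM reports")
    report_df, metas, calibration_df = simulate_srm_report(
        truth, bundle, params, constants
    )
    measurements = parse_report(report_df)
    quant = quantify_report(
        measurements,
        metas,
        bundle.peptide_to_protein,
        bundle.peptide_to_standard,
        bundle.standard_mw,
        constants,
        exclude_peptides=set(bundle.modifiable_peptides.values()),
    )
    quant_summary = replicate_summary(quant)
    ptm = ptm_report(
        measurements,
        metas,
        bundle.peptide_to_protein,
        modifiable_peptides=set(bundle.modifiable_peptides.values()),
    )

    log.info("quantifying amino-acid pools")
    aa_areas, aa_standards = simulate_amino_acid_reports(truth, params, constants)
    curves = {
        analyte: fit_calibration(
            list(zip(sub["concentration_um"], sub["area"])), analyte
        )
        for analyte, sub in aa_standards.groupby("analyte")
    }
    aa_metas = metabolite_sample_metas(truth, params)
    pools = []
    for sid, sub in aa_areas.groupby("sample_id"):
        areas = dict(zip(sub["analyte"], sub["area"]))
        pools.extend(quantify_amino_acids(areas, curves, aa_metas[sid], constants))
    pool_df = pools_to_frame(pools, aa_metas)
    wt_fc = base_mean_fold_changes(pool_df[pool_df["strain"] == WILD_TYPE])
    contrasts = {
        strain: strain_contrast(pool_df, strain, WILD_TYPE)
        for strain in (DELTA_NIFLA, NIFK_TRUNC)
    }

    log.info("physiology calculations")
    culture = simulate_physiology(truth, params)
    physiology_results = {}
    for strain in STRAINS:
        sub = culture[culture["strain"] == strain].sort_values("time_h")
        rates = acetylene_reduction_rate(
            sub["time_h"], sub["ethylene_area"], sub["acetylene_area"],
            sub["od600"], params.gc_nmol_per_area, params.culture_volume_ml,
        )
        physiology_results[strain] = rates
    wt_culture = culture[culture["strain"] == WILD_TYPE].sort_values("time_h")
    late_growth = growth_rate(
        wt_culture["time_h"], wt_culture["od600"], window=(10.0, 12.5)
    )

    log.info("resource allocation")
    allocations = {}
    for strain in (WILD_TYPE, NIFK_TRUNC):
        summary = quant_summary[quant_summary["strain"] == strain]
        times = sorted(summary["time_h"].unique())
        rates = []
        copies_at_end = {}
        for protein, sub in summary.groupby("protein"):
            if not protein.startswith("Nif"):
                continue
            series = sub.sort_values("time_h")
            rates.append(
                synthesis_rate(
                    series["time_h"].tolist(),
                    series["copies_per_cell"].tolist(),
                    config.window_h,
                    protein,
                )
            )
            copies_at_end[protein] = float(
                series[series["time_h"] == config.window_h[1]]["copies_per_cell"].iloc[0]
            )
        pools_5h = pool_df[
            (pool_df["strain"] == strain) & (pool_df["time_h"] == 5.0)
        ]
        pool_molecules = (
            pools_5h.groupby("amino_acid")["molecules_per_cell"].mean().to_dict()
        )
        nif_structural = {
            k: v for k, v in copies_at_end.items() if k in NITROGENASE_STOICHIOMETRY
        }
        allocations[strain] = allocation_summary(
            rates,
            proteome,
            {**copies_at_end, **nif_structural},
            pool_molecules,
            constants=constants,
        )
        allocations[strain]["growth_rate_10_12.5_per_h"] = late_growth.rate_per_h

    results = {
        "truth": truth,
        "bundle": bundle,
        "quant": quant,
        "quant_summary": quant_summary,
        "ptm": ptm,
        "pools": pool_df,
        "wt_fold_changes": wt_fc,
        "contrasts": contrasts,
        "culture": culture,
        "acetylene_rates": physiology_results,
        "allocations": allocations,
    }

    if write_outputs:
        _write_table(quant_summary, outdir / "protein_copies.tsv", config)
        _write_table(ptm, outdir / "ptm_occupancy.tsv", config)
        _write_table(pool_df, outdir / "amino_acid_pools.tsv", config)
        _write_table(wt_fc, outdir / "pool_fold_changes_wt.tsv", config)
        for strain, df in contrasts.items():
            _write_table(df, outdir / f"pool_contrast_{strain}.tsv", config)
        _write_table(culture, outdir / "culture_timecourse.tsv", config)
        for strain, df in physiology_results.items():
            _write_table(df, outdir / f"acetylene_rates_{strain}.tsv", config)
        with open(outdir / "allocation_summary.json", "w") as fh:
            json.dump(
                {
                    "version": __version__,
                    "seed": config.seed,
                    "config_hash": config.config_hash(),
                    "strains": allocations,
                },
                fh,
                indent=2,
                default=float,
            )
        log.info("outputs written to %s", outdir)
    return results
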