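"""Synthetic scenario generator: determinism, truth structure, recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from nifquant.simulate import (
    DELTA_NIFLA,
    MODIFIABLE_PEPTIDES,
    NIFK_TRUNC,
    STRAINS,
    WILD_TYPE,
    ScenarioParams,
    build_sample_metas,
    design_standards,
    make_proteome,
    simulate_amino_acid_reports,
    simulate_physiology,
    simulate_srm_report,
    simulate_timecourse,
)
from nifquant.srm import parse_report, quantify_report


class TestDeterminism:
    def test_same_seed_identical_report(self, truth, bundle):
        r1, _, c1 = simulate_srm_report(truth, bundle)
        r2, _, c2 = simulate_srm_report(truth, bundle)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_different_seed_same_skeleton_different_noise(self, truth, bundle):
        p2 = replace(truth.params, seed=truth.params.seed + 1)
        t2 = simulate_timecourse(p2)
        # the noiseless truth (proteome, copies, pools) is seed-independent
        assert [e.sequence for e in truth.proteome] == [
            e.sequence for e in t2.proteome
        ]
        pd.testing.assert_frame_equal(truth.protein_copies, t2.protein_copies)
        pd.testing.assert_frame_equal(truth.aa_pools, t2.aa_pools)
        # but the measured areas differ
        r1, _, _ = simulate_srm_report(truth, bundle)
        r2, _, _ = simulate_srm_report(t2, bundle)
        assert not np.allclose(r1["area"], r2["area"])

    def test_scenario_params_validation(self):
        with pytest.raises(ValueError):
            ScenarioParams(od0=0.0)
        with pytest.raises(ValueError):
            ScenarioParams(replicates=0)


class TestProteome:
    def test_targets_and_background_present(self, truth):
        ids = {e.id for e in truth.proteome}
        assert {"NifH", "NifD", "NifK", "GlnB", "GlnK", "GS"} <= ids
        assert sum(1 for i in ids if i.startswith("BG")) == 12

    def test_modifiable_peptides_embedded_and_released(self, truth):
        from nifquant.sequences import digest_trypsin

        by_id = {e.id: e for e in truth.proteome}
        for pid, tag in MODIFIABLE_PEPTIDES.items():
            peps = {p.sequence for p in digest_trypsin(by_id[pid].sequence, 0)}
            assert tag in peps


class TestTruthStructure:
    def test_nh4_nearly_exhausted_by_5h(self, truth):
        wt = truth.nh4_um[truth.nh4_um["strain"] == WILD_TYPE]
        nh4_5h = wt.loc[wt["time_h"] == 5.0, "nh4_um"].iloc[0]
        assert nh4_5h < 0.03 * truth.params.initial_nh4_um

    def test_delta_nifla_never_expresses_nif(self, truth):
        sub = truth.protein_copies[
            (truth.protein_copies["strain"] == DELTA_NIFLA)
            & (truth.protein_copies["protein"].str.startswith("Nif"))
        ]
        assert (sub["copies"] == 0).all()

    def test_truncation_mutant_reduced_but_nonzero_nif(self, truth):
        piv_wt = truth.copies_lookup(WILD_TYPE)
        piv_tr = truth.copies_lookup(NIFK_TRUNC)
        ratio = piv_tr.loc[12.5, "NifK"] / piv_wt.loc[12.5, "NifK"]
        assert ratio == pytest.approx(truth.params.nif_feedback_factor, rel=1e-9)

    def test_structural_over_accessory_ratio_increases(self, truth):
        piv = truth.copies_lookup(WILD_TYPE)
        ratios = piv["NifK"] / piv["NifB"]
        late = ratios.loc[[7.5, 10.0, 12.5]].to_numpy()
        assert np.all(np.diff(late) > 0)

    def test_only_wild_type_has_active_enzymes(self, truth):
        enz = truth.enzymes
        for strain in (DELTA_NIFLA, NIFK_TRUNC):
            assert (enz.loc[enz["strain"] == strain, "active"] == 0).all()
        wt_final = enz[(enz["strain"] == WILD_TYPE) & (enz["time_h"] == 12.5)]
        assert wt_final["active"].iloc[0] > 10_000

    def test_mutants_produce_no_ethylene(self, truth):
        eth = truth.ethylene
        for strain in (DELTA_NIFLA, NIFK_TRUNC):
            assert (eth.loc[eth["strain"] == strain, "cumulative_nmol"] == 0).all()
        wt = eth[eth["strain"] == WILD_TYPE].sort_values("time_h")
        assert wt["cumulative_nmol"].is_monotonic_increasing
        assert wt["cumulative_nmol"].iloc[-1] > 0

    def test_wild_type_resumes_growth_after_starvation(self, truth):
        od = truth.od.pivot(index="time_h", columns="strain", values="od600")
        assert od.loc[12.5, WILD_TYPE] > od.loc[7.5, WILD_TYPE] * 1.05
        # non-fixers stay arrested
        assert od.loc[12.5, DELTA_NIFLA] == pytest.approx(
            od.loc[7.5, DELTA_NIFLA], rel=0.01
        )

    def test_ptm_fractions_bounded_and_rise_with_starvation(self, truth):
        ptm = truth.ptm_fractions
        assert ptm["fraction"].between(0, 1).all()
        wt_glnk = ptm[
            (ptm["strain"] == WILD_TYPE) & (ptm["protein"] == "GlnK")
        ].sort_values("time_h")["fraction"]
        assert wt_glnk.iloc[0] < 0.5 < wt_glnk.iloc[-1]
        assert wt_glnk.iloc[-1] > 0.95

    def test_glutamate_declines_proline_accumulates(self, truth):
        pools = truth.aa_pools[truth.aa_pools["strain"] == WILD_TYPE]
        glu = pools[pools["amino_acid"] == "E"].sort_values("time_h")
        pro = pools[pools["amino_acid"] == "P"].sort_values("time_h")
        assert glu["concentration_m"].iloc[0] == pytest.approx(0.07, rel=0.05)
        assert glu["concentration_m"].iloc[-1] < 0.3 * glu["concentration_m"].iloc[0]
        assert pro["concentration_m"].iloc[-1] > 1.5 * pro["concentration_m"].iloc[0]

    def test_zero_initial_nh4_starves_immediately(self):
        p = ScenarioParams(seed=1, initial_nh4_um=0.0)
        t = simulate_timecourse(p)
        od = t.od[t.od["strain"] == DELTA_NIFLA].sort_values("time_h")
        # no fixed N and no nitrogenase: OD never leaves its inoculum
        assert od["od600"].iloc[-1] == pytest.approx(p.od0, rel=1e-6)


class TestStandardsBundle:
    def test_two_quantotypic_peptides_per_protein(self, bundle):
        counts: dict[str, int] = {}
        for pep, protein in bundle.peptide_to_protein.items():
            if pep not in bundle.modifiable_peptides.values():
                counts[protein] = counts.get(protein, 0) + 1
        assert all(n == 2 for n in counts.values())

    def test_modifiable_peptides_in_bundle(self, bundle):
        assert bundle.modifiable_peptides == MODIFIABLE_PEPTIDES

    def test_standard_grouping(self, bundle):
        for pep, std in bundle.peptide_to_standard.items():
            protein = bundle.peptide_to_protein[pep]
            groups = {
                "QNif1": {"NifH", "NifD", "NifK"},
                "QNif2": {"NifB", "NifE", "NifN", "NifA"},
                "QNtr": {"GlnB", "GlnK", "GS"},
            }
            assert protein in groups[std]

    def test_three_transitions_per_peptide(self, bundle):
        for pep, ions in bundle.transitions.items():
            assert len(ions) == 3
            assert all(i.startswith("y") for i in ions)


class TestNoiselessRecovery:
    def test_quantification_recovers_truth_exactly(self, bundle):
        """With zero noise the full SRM round trip is an identity."""
        p = ScenarioParams(seed=1, noise_cv_area=0.0, replicates=1)
        truth = simulate_timecourse(p)
        report, metas, _ = simulate_srm_report(truth, bundle, p)
        quant = quantify_report(
            parse_report(report),
            metas,
            bundle.peptide_to_protein,
            bundle.peptide_to_standard,
            bundle.standard_mw,
            exclude_peptides=set(bundle.modifiable_peptides.values()),
        )
        piv = truth.copies_lookup(WILD_TYPE)
        wt = quant[quant["strain"] == WILD_TYPE]
        for _, row in wt.iterrows():
            expected = piv.loc[row["time_h"], row["protein"]]
            if expected == 0:
                assert row["copies_per_cell"] == pytest.approx(0.0, abs=1e-9)
            else:
                assert row["copies_per_cell"] == pytest.approx(expected, rel=1e-9)

    def test_standard_concentration_cancels(self, bundle):
        """Halving the spiked standard halves heavy areas but leaves the
        recovered copy numbers unchanged (ratio method)."""
        base = ScenarioParams(seed=1, noise_cv_area=0.0, replicates=1)
        halved = replace(
            base,
            standard_concentrations={
                k: v / 2 for k, v in base.standard_concentrations.items()
            },
        )
        out = {}
        for tag, p in (("base", base), ("halved", halved)):
            truth = simulate_timecourse(p)
            report, metas, _ = simulate_srm_report(truth, bundle, p)
            out[tag] = quantify_report(
                parse_report(report), metas,
                bundle.peptide_to_protein, bundle.peptide_to_standard,
                bundle.standard_mw,
                exclude_peptides=set(bundle.modifiable_peptides.values()),
            ).sort_values(["protein", "sample_id"], ignore_index=True)
        assert np.allclose(
            out["base"]["copies_per_cell"], out["halved"]["copies_per_cell"]
        )


class TestMeasurementChannels:
    def test_srm_report_parses_cleanly(self, truth, bundle):
        report, metas, cal = simulate_srm_report(truth, bundle)
        records = parse_report(report, set(bundle.peptide_to_protein))
        assert len(records) == len(report)
        assert set(report["sample_id"]) == set(metas)
        assert (cal["light_area"] >= 0).all()
        assert (cal.loc[cal["dilution"] == 0, "dilution"] == 0).all()

    def test_physiology_channels(self, truth):
        phys = simulate_physiology(truth)
        assert set(phys["strain"]) == set(STRAINS)
        wt = phys[phys["strain"] == WILD_TYPE].sort_values("time_h")
        # acetylene decays geometrically with sampling events
        acet = wt["acetylene_area"].to_numpy()
        assert np.allclose(
            acet[1:] / acet[:-1], truth.params.gc_sampling_dilution
        )
        # absorbance tracks NH4 decline
        assert wt["nh4_abs690"].iloc[0] > wt["nh4_abs690"].iloc[-1]

    def test_amino_acid_standards_linear_except_droop(self, truth):
        _, standards = simulate_amino_acid_reports(truth)
        for aa, sub in standards.groupby("analyte"):
            sub = sub.sort_values("concentration_um")
            hi = sub[sub["concentration_um"] >= 2.0]
            slopes = hi["area"] / hi["concentration_um"]
            assert np.allclose(slopes, slopes.iloc[0], rtol=1e-9)
            lo = sub[sub["concentration_um"] < 2.0]
            low_slopes = lo["area"] / lo["concentration_um"]
            if aa in ("N", "D", "Q"):
                assert (low_slopes < slopes.iloc[0] * 0.999).all()
            else:
                assert np.allclose(low_slopes, slopes.iloc[0], rtol=1e-9)

    def test_sample_metas_cover_grid(self, truth):
        metas = build_sample_metas(truth)
        expected = len(STRAINS) * len(truth.times_h) * truth.params.replicates
        assert len(metas) == expected
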