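"""Proteotypic peptide filtering, concatamer assembly, transition lists."""

import random

import pytest

from nifquant.constants import HEAVY_SHIFT_KR
from nifquant.design import (
    CandidateFilterParams,
    DesignError,
    QconCATDesign,
    QconCATSegment,
    TransitionListParams,
    assemble_qconcat,
    build_transition_list,
    native_context,
    select_candidates,
    verify_release,
)
from nifquant.sequences import ProteinEntry, digest_trypsin


def toy_proteome():
    return [
        ProteinEntry("NifA", "MELKGAFTGAVRLQDLLK"),
        ProteinEntry("NifD", "MAKGVVFGPIKDEAFTR"),
        ProteinEntry("Other", "MELKAHGTLLKGVVKAPR"),
    ]


def eval_for(evals, sequence):
    return next(e for e in evals if e.peptide.sequence == sequence)


class TestSelectCandidates:
    def test_forbidden_residue(self):
        proteome = toy_proteome()
        evals = select_candidates(proteome[2], proteome)
        e = eval_for(evals, "AHGTLLK")
        assert any(f.startswith("forbidden_residue") and "H" in f for f in e.hard_failures)

    def test_length_filter(self):
        proteome = toy_proteome()
        evals = select_candidates(proteome[2], proteome)
        e = eval_for(evals, "GVVK")
        assert "length" in e.hard_failures

    def test_exemplar_peptides_pass_residue_and_length_filters(self):
        proteome = toy_proteome()
        for pid, pep in [("NifA", "GAFTGAVR"), ("NifD", "GVVFGPIK")]:
            entry = next(e for e in proteome if e.id == pid)
            ev = eval_for(select_candidates(entry, proteome), pep)
            assert "length" not in ev.hard_failures
            assert not any(
                f.startswith("forbidden_residue") for f in ev.hard_failures
            )

    def test_absent_protein_rejected(self):
        proteome = toy_proteome()
        with pytest.raises(ValueError, match="not present"):
            select_candidates(ProteinEntry("X", "GAK"), proteome)

    def test_uniqueness_brute_force_oracle(self):
        """Indexed uniqueness matches scanning every tryptic peptide."""
        rng = random.Random(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        proteome = [
            ProteinEntry(f"P{i}", "".join(rng.choices(aa, k=80))) for i in range(6)
        ]
        params = CandidateFilterParams()
        for entry in proteome:
            evals = select_candidates(entry, proteome, params)
            for ev in evals:
                count = 0
                for other in proteome:
                    for pep in digest_trypsin(other.sequence, 1):
                        if pep.sequence == ev.peptide.sequence:
                            count += 1
                assert ("not_unique" in ev.hard_failures) == (count != 1)

    def test_soft_filters_relaxed_in_order(self):
        # every candidate has a KK/RR context -> double_basic must be relaxed
        proteome = [ProteinEntry("P", "MKKGAFTGAVELKKGADLTGAVEIKK")]
        params = CandidateFilterParams(min_candidates=1)
        evals = select_candidates(proteome[0], proteome, params)
        passed = [e for e in evals if e.passed]
        assert passed and all("double_basic" in e.soft_failures for e in passed)
        assert not any("proline_adjacent" in e.soft_failures for e in passed)

    def test_no_hard_filter_violations_among_passing(self):
        proteome = toy_proteome()
        for entry in proteome:
            for ev in select_candidates(entry, proteome):
                if ev.passed:
                    assert not ev.hard_failures


class TestAssembly:
    def test_single_segment_release(self):
        design = assemble_qconcat([("EIK", "GAFTGAVR", "LQD")], name="Q1")
        assert "EIKGAFTGAVRLQD" in design.full_sequence
        released = [p.sequence for p in digest_trypsin(design.full_sequence, 0)]
        assert released.count("GAFTGAVR") == 1

    def test_terminal_bsa_controls_released_first_and_last(self):
        design = assemble_qconcat(
            [("EIK", "GAFTGAVR", "LQK"), ("AGK", "GVVFGPIK", "DEK")],
            bsa_controls=("LVNELTEFAK", "HLVDEPQNLIK"),
        )
        released = [p.sequence for p in digest_trypsin(design.full_sequence, 0)]
        assert released[0] == "LVNELTEFAK"
        assert released[-1] == "HLVDEPQNLIK"

    def test_empty_peptide_list(self):
        with pytest.raises(DesignError, match="empty"):
            assemble_qconcat([])

    def test_proline_flank_blocks_release(self):
        with pytest.raises(DesignError, match="GAFTGAVR"):
            assemble_qconcat([("EIK", "GAFTGAVR", "PQD")])

    def test_duplicated_signature_peptide_flagged(self):
        design = QconCATDesign(
            "dup",
            (
                QconCATSegment("EIK", "GAFTGAVR", "LQK"),
                QconCATSegment("AGK", "GAFTGAVR", "DEK"),
            ),
            ("LVNELTEFAK", "HLVDEPQNLIK"),
        )
        assert verify_release(design)["GAFTGAVR"] is False

    def test_bundle_designs_release_all_signatures(self, bundle):
        for design in bundle.designs.values():
            release = verify_release(design)
            assert all(release[p] for p in design.signature_peptides)

    def test_native_context_extraction(self):
        parent = ProteinEntry("NifA", "MELKGAFTGAVRLQDLLK")
        pep = next(
            p for p in digest_trypsin(parent.sequence, 0, "NifA")
            if p.sequence == "GAFTGAVR"
        )
        assert native_context(pep, parent) == ("ELK", "LQD")

    def test_random_toy_designs_release_invariant(self):
        """Peptides drawn from random proteins are always released intact."""
        rng = random.Random(5)
        aa = "ADEFGILNQSTVWY"  # no K/R/P so cut-site structure is controlled
        n_ok = 0
        for _ in range(100):
            segments = []
            for _ in range(rng.randint(2, 6)):
                pep = "".join(rng.choices(aa, k=rng.randint(5, 12))) + rng.choice("KR")
                up = "".join(rng.choices(aa, k=2)) + rng.choice("KR")
                down = "".join(rng.choices(aa, k=3))
                segments.append((up, pep, down))
            if len({s[1] for s in segments}) < len(segments):
                continue
            design = assemble_qconcat(segments, name="rand")
            release = verify_release(design)
            assert all(release[p] for p in design.signature_peptides)
            n_ok += 1
        assert n_ok >= 90


class TestTransitionList:
    def test_light_heavy_pairs_differ_by_label_shift(self, bundle):
        for design in bundle.designs.values():
            records = build_transition_list(design)
            by_key = {}
            for r in records:
                by_key.setdefault((r.peptide, r.product_ion), {})[r.label_state] = r
            for (pep, ion), pair in by_key.items():
                light, heavy = pair["light"], pair["heavy"]
                n_kr = sum(pep.count(x) for x in "KR")
                expected = n_kr * HEAVY_SHIFT_KR / light.precursor_charge
                assert heavy.precursor_mz - light.precursor_mz == pytest.approx(
                    expected, abs=1e-6
                )

    def test_known_mz_values(self):
        design = assemble_qconcat([("EIK", "GAFTGAVR", "LQD")])
        records = build_transition_list(design, params=TransitionListParams(n_products=7))
        light = [r for r in records if r.label_state == "light" and r.peptide == "GAFTGAVR"]
        heavy = [r for r in records if r.label_state == "heavy" and r.peptide == "GAFTGAVR"]
        assert light[0].precursor_mz == pytest.approx(389.7139, abs=1e-3)
        assert heavy[0].precursor_mz == pytest.approx(393.7210, abs=1e-3)
        y1 = [r for r in light if r.product_ion == "y1"]
        assert y1 and y1[0].product_mz == pytest.approx(175.1190, abs=1e-3)

    def test_collision_energy_linear_map(self):
        design = assemble_qconcat([("EIK", "GAFTGAVR", "LQD")])
        p = TransitionListParams(ce_slope=0.05, ce_intercept=4.0)
        rec = build_transition_list(design, params=p)[0]
        assert rec.collision_energy == pytest.approx(
            0.05 * rec.precursor_mz + 4.0, abs=1e-9
        )
        assert rec.dwell_time_ms == 3.0

    def test_no_in_range_products_error(self):
        design = assemble_qconcat([("EIK", "GAFTGAVR", "LQD")])
        with pytest.raises(DesignError, match="y-ions"):
            build_transition_list(
                design, params=TransitionListParams(mz_min=2000.0, mz_max=3000.0)
            )
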