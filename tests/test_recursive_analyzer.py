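"""Recursive extraction, degeneracy handling, validation, overlap, strategies."""

from dataclasses import replace

import numpy as np
import pytest

from jdeconv import (
    AnalysisOptions,
    CouplingSpec,
    LineShape,
    OverlapTooSevereError,
    Spectrum1D,
    analyze_overlapped,
    extract_couplings,
    group_degenerate,
    post_degeneracy_search,
    preprocess,
    strategy_search,
    synth_multiplet,
    validate_by_reconstruction,
)
from tests.conftest import build_two_multiplets, flat_j_list


class TestExtractCouplings:
    def test_overlapping_dd_is_not_read_as_triplet(self, dd_632_422):
        # 6.32 / 4.22 Hz at 2.7 Hz line width: the naive visual reading is a
        # 5.27 Hz triplet; deconvolution resolves the 2 Hz difference
        result = extract_couplings(dd_632_422)
        got = flat_j_list(result)
        assert len(got) == 2
        assert abs(got[0] - 6.32) <= 0.1
        assert abs(got[1] - 4.22) <= 0.1
        assert result.multiplicity == "dd"

    def test_ddd_recovered(self):
        truth = [14.71, 4.77, 2.89]
        spec = synth_multiplet(
            0.0, [CouplingSpec(j) for j in truth],
            LineShape("lorentzian", 1.2), step_hz=0.05,
        )
        got = flat_j_list(extract_couplings(spec))
        assert len(got) == 3
        assert all(abs(a - b) <= 0.1 for a, b in zip(got, truth))

    def test_pure_singlet_yields_empty_couplings(self):
        spec = synth_multiplet(0.0, [], LineShape("lorentzian", 1.0), step_hz=0.05)
        result = extract_couplings(spec)
        assert result.couplings == []
        assert result.multiplicity == "s"

    def test_sub_linewidth_doublet_found_and_flagged(self):
        # a 1.2 Hz splitting under a 2 Hz line is invisible by eye
        spec = synth_multiplet(
            0.0, [CouplingSpec(1.2)], LineShape("lorentzian", 2.0), step_hz=0.1
        )
        result = extract_couplings(spec)
        got = flat_j_list(result)
        assert len(got) == 1
        assert abs(got[0] - 1.2) <= 0.1
        assert any("unresolved" in f for f in result.flags)

    def test_triplet_found_via_repeated_extraction(self):
        spec = synth_multiplet(
            0.0, [CouplingSpec(7.0, degeneracy=2)],
            LineShape("lorentzian", 1.0), step_hz=0.05,
        )
        result = extract_couplings(spec)
        assert result.multiplicity == "t"
        assert result.couplings[0].degeneracy == 2
        assert abs(result.couplings[0].j_hz - 7.0) <= 0.1

    def test_region_too_narrow_for_floor_rejected(self):
        spec = Spectrum1D(np.ones(10), 0.0, 0.1)
        with pytest.raises(ValueError, match="too narrow"):
            extract_couplings(spec, AnalysisOptions(j_floor_hz=1.0))

    def test_spin_map_analyses_quadrupolar_quartet(self, quartet_s32):
        result = extract_couplings(
            quartet_s32, AnalysisOptions(spin_map=[(1.5, 1)])
        )
        assert len(result.couplings) == 1
        c = result.couplings[0]
        assert c.spin == 1.5
        assert abs(c.j_hz - 81.6) <= 0.25
        assert result.validation_score >= 0.99

    def test_spin_half_misanalysis_doubles_the_coupling(self, quartet_s32):
        # reading the 1:1:1:1 quartet as spin-1/2 structure gives a dd whose
        # larger coupling is exactly twice the true one
        result = extract_couplings(quartet_s32)
        got = flat_j_list(result)
        assert len(got) == 2
        assert abs(got[0] - 2 * got[1]) <= 0.5
        assert abs(got[0] - 2 * 81.6) <= 0.5


class TestGroupDegenerate:
    def test_close_pair_becomes_triplet(self):
        specs = group_degenerate([7.01, 6.98], 0.5)
        assert len(specs) == 1
        assert specs[0].degeneracy == 2
        assert specs[0].j_hz == pytest.approx(6.995)

    def test_empty_input(self):
        assert group_degenerate([], 0.5) == []

    def test_distinct_pair_stays_distinct(self):
        specs = group_degenerate([6.32, 4.22], 0.5)
        assert [s.degeneracy for s in specs] == [1, 1]
        assert [round(s.j_hz, 2) for s in specs] == [6.32, 4.22]


class TestValidation:
    def test_self_consistent_result_passes(self, dd_632_422):
        result = extract_couplings(dd_632_422)
        score, passed = validate_by_reconstruction(result, dd_632_422)
        assert passed and score >= 0.99

    def test_score_drops_when_true_coupling_deleted(self, dd_632_422):
        result = extract_couplings(dd_632_422)
        full, _ = validate_by_reconstruction(result, dd_632_422)
        for i in range(2):
            partial = result.replace(
                couplings=[c for k, c in enumerate(result.couplings) if k != i]
            )
            score, _ = validate_by_reconstruction(partial, dd_632_422)
            assert score < full

    def test_score_drops_when_false_coupling_added(self, dd_632_422):
        result = extract_couplings(dd_632_422)
        full, _ = validate_by_reconstruction(result, dd_632_422)
        inflated = result.replace(
            couplings=result.couplings + [CouplingSpec(9.0)]
        )
        score, _ = validate_by_reconstruction(inflated, dd_632_422)
        assert score < full

    def test_empty_region_scores_zero(self, dd_632_422):
        result = extract_couplings(dd_632_422)
        zeros = dd_632_422.with_amplitudes(np.zeros(len(dd_632_422)))
        score, passed = validate_by_reconstruction(result, zeros)
        assert score == 0.0 and not passed


class TestPostDegeneracySearch:
    def test_undercounted_triplet_of_heptets_recovered(self):
        # triplet (7.0 Hz) of heptets (1.3 Hz): the outermost lines are so
        # weak that a first pass under-counts both multiplicities; the
        # search must climb back to t x hept
        from jdeconv.multiplet_model import MultipletResult

        spec = synth_multiplet(
            0.0,
            [CouplingSpec(7.0, degeneracy=2), CouplingSpec(1.3, degeneracy=6)],
            LineShape("lorentzian", 0.6),
            step_hz=0.05,
        )
        singlet = synth_multiplet(
            0.0, [], LineShape("lorentzian", 0.6), step_hz=0.05
        )
        undercounted = MultipletResult(
            center_hz=spec.centroid_hz(),
            couplings=[CouplingSpec(7.0), CouplingSpec(1.3, degeneracy=5)],
            residual_singlet=singlet,
        )
        score0, passed0 = validate_by_reconstruction(undercounted, spec)
        assert not passed0  # the missing outer lines are a visible mismatch
        fixed = post_degeneracy_search(undercounted, spec)
        by_j = fixed.sorted_couplings()
        assert by_j[0].degeneracy == 2 and abs(by_j[0].j_hz - 7.0) <= 0.1
        assert by_j[1].degeneracy == 6 and abs(by_j[1].j_hz - 1.3) <= 0.1
        assert fixed.validation_score >= 0.99

    def test_full_pipeline_solves_triplet_of_heptets(self):
        spec = synth_multiplet(
            0.0,
            [CouplingSpec(7.0, degeneracy=2), CouplingSpec(1.3, degeneracy=6)],
            LineShape("lorentzian", 0.6),
            step_hz=0.05,
        )
        best = strategy_search(spec)[0]
        degs = [c.degeneracy for c in best.sorted_couplings()]
        js = [c.j_hz for c in best.sorted_couplings()]
        assert degs == [2, 6]
        assert abs(js[0] - 7.0) <= 0.1 and abs(js[1] - 1.3) <= 0.1
        assert best.validation_score >= 0.99

    def test_correct_dd_left_unchanged(self, dd_632_422):
        result = extract_couplings(dd_632_422)
        fixed = post_degeneracy_search(result, dd_632_422)
        assert [(c.j_hz, c.degeneracy) for c in fixed.sorted_couplings()] == [
            (c.j_hz, c.degeneracy) for c in result.sorted_couplings()
        ]

    def test_quartet_reported_as_three_near_equal_j_merges(self):
        spec = synth_multiplet(
            0.0, [CouplingSpec(7.0, degeneracy=3)],
            LineShape("lorentzian", 1.0), step_hz=0.05,
        )
        correct = extract_couplings(spec)
        # imitate a run that returned three almost identical couplings
        broken = correct.replace(
            couplings=[CouplingSpec(7.05), CouplingSpec(7.0), CouplingSpec(6.95)]
        )
        fixed = post_degeneracy_search(broken, spec)
        assert len(fixed.couplings) == 1
        assert fixed.couplings[0].degeneracy == 3
        assert fixed.validation_score >= 0.99


class TestAnalyzeOverlapped:
    def test_partially_overlapping_multiplets_separated(self):
        ja = [14.71, 4.77, 2.89]
        jb = [13.77, 6.15, 3.91, 2.93]
        region, _, _ = build_two_multiplets(ja, jb, overlap_hz=3.0)
        opts = AnalysisOptions(overlap_fraction=0.5)
        res_a = analyze_overlapped(region, opts, direction="L2R")
        res_b = analyze_overlapped(region, opts, direction="R2L")
        got_a, got_b = flat_j_list(res_a), flat_j_list(res_b)
        assert len(got_a) == 3 and len(got_b) == 4
        assert all(abs(a - b) <= 0.1 for a, b in zip(got_a, sorted(ja, reverse=True)))
        assert all(abs(a - b) <= 0.1 for a, b in zip(got_b, sorted(jb, reverse=True)))

    def test_full_fraction_reduces_to_plain_extraction(self, dd_632_422):
        plain = extract_couplings(dd_632_422)
        viaf1 = extract_couplings(
            dd_632_422, AnalysisOptions(overlap_fraction=1.0)
        )
        assert flat_j_list(plain) == flat_j_list(viaf1)

    def test_overlap_beyond_largest_coupling_raises(self):
        region, _, _ = build_two_multiplets([4.0, 2.5], [3.5, 2.2], overlap_hz=6.0)
        with pytest.raises(OverlapTooSevereError):
            analyze_overlapped(
                region, AnalysisOptions(overlap_fraction=0.5), direction="L2R"
            )

    def test_missing_fraction_rejected(self, dd_632_422):
        with pytest.raises(ValueError):
            analyze_overlapped(dd_632_422, AnalysisOptions())


class TestStrategySearch:
    def test_misphased_doublet_prefers_no_symmetrization(self):
        spec = synth_multiplet(
            0.0, [CouplingSpec(8.0)],
            LineShape("lorentzian", 1.0, phase_deg=40.0), step_hz=0.05,
        )
        ranked = strategy_search(spec)
        def symmetrized(r):
            return r.strategy_used["symmetrize_input"] or r.strategy_used["symmetrize_each_step"]
        best_off = max(r.validation_score for r in ranked if not symmetrized(r))
        best_on = max(r.validation_score for r in ranked if symmetrized(r))
        assert best_off > best_on
        assert not symmetrized(ranked[0])

    def test_clean_dd_strategies_agree_on_j(self, dd_632_422):
        ranked = strategy_search(dd_632_422)
        reference = flat_j_list(ranked[0])
        for r in ranked:
            if r.validation_score >= 0.99:
                got = flat_j_list(r)
                assert len(got) == len(reference)
                assert all(abs(a - b) <= 0.1 for a, b in zip(got, reference))

    def test_symmetric_input_indifferent_to_symmetrization(self):
        spec = synth_multiplet(
            0.0, [CouplingSpec(6.0)], LineShape("lorentzian", 1.0), step_hz=0.05
        )
        on = extract_couplings(spec, AnalysisOptions(symmetrize_input=True))
        off = extract_couplings(spec, AnalysisOptions(symmetrize_input=False))
        assert flat_j_list(on) == pytest.approx(flat_j_list(off), abs=1e-6)

    def test_empty_option_grid_rejected(self, dd_632_422):
        with pytest.raises(ValueError):
            strategy_search(dd_632_422, option_grid=[])

    def test_results_sorted_and_deterministic(self, dd_632_422):
        a = strategy_search(dd_632_422)
        b = strategy_search(dd_632_422)
        scores = [r.validation_score for r in a]
        assert scores == sorted(scores, reverse=True)
        assert [flat_j_list(r) for r in a] == [flat_j_list(r) for r in b]


class TestLineshapeIndependence:
    def test_same_j_across_line_shapes(self):
        # extraction needs only an equally split pattern, not a particular
        # line shape: Lorentzian, Gaussian, misphased, second derivative
        couplings = [CouplingSpec(6.32), CouplingSpec(4.22)]
        opts = AnalysisOptions(symmetrize_each_step=False)
        lor = synth_multiplet(0.0, couplings, LineShape("lorentzian", 1.2), step_hz=0.05)
        variants = {
            "lorentzian": lor,
            "gaussian": synth_multiplet(
                0.0, couplings, LineShape("gaussian", 1.2), step_hz=0.05
            ),
            "misphased": synth_multiplet(
                0.0, couplings, LineShape("lorentzian", 1.2, phase_deg=30.0),
                step_hz=0.05,
            ),
            "second_derivative": preprocess(lor, second_derivative=True),
        }
        step = lor.step_hz
        results = {k: flat_j_list(extract_couplings(v, opts)) for k, v in variants.items()}
        for name, got in results.items():
            assert len(got) == 2, name
            assert abs(got[0] - results["lorentzian"][0]) <= step, name
            assert abs(got[1] - results["lorentzian"][1]) <= step, name
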