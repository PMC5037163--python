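import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emcoloc import (
    DistanceBand,
    EdgeWeightSpec,
    PointPattern,
    StudyWindow,
    UndefinedCoefficientError,
    cc1_aggregate,
    cc2,
    cc3,
    compute_coefficients,
    find_colocalizing_pairs,
    summary_coefficients,
    verify_identities,
)
from emcoloc.coefficients import ColocalizationCoefficients

from oracles import brute_cc2, brute_cc3, brute_pairs, random_pattern

WINDOW = StudyWindow(2000.0, 2000.0)
BAND = DistanceBand(25.0, 125.0)


class TestPairFinding:
    def test_worked_example_adjacency(self, example_stack, example_band):
        ps = find_colocalizing_pairs(example_stack[0], example_band)
        assert len(ps.pairs) == 4
        assert ps.n_col_a == 3 and ps.n_col_b == 2
        assert ps.counts_a.tolist() == [0, 2, 1, 1]
        assert ps.counts_b.tolist() == [3, 0, 1]

    def test_half_open_interval_is_strict_at_upper_bound(self):
        window = StudyWindow(1000.0, 1000.0)
        band = DistanceBand(25.0, 125.0)
        at_hi = PointPattern("x", window, [[0.0, 0.0]], [[125.0, 0.0]])
        assert find_colocalizing_pairs(at_hi, band).pairs == ()
        at_lo = PointPattern("x", window, [[0.0, 0.0]], [[25.0, 0.0]])
        assert find_colocalizing_pairs(at_lo, band).pairs == ((0, 0),)

    def test_empty_patterns_yield_empty_pair_set(self):
        empty = PointPattern("x", WINDOW)
        ps = find_colocalizing_pairs(empty, BAND)
        assert ps.pairs == () and ps.n_col_a == 0 and ps.n_col_b == 0

    def test_matches_double_loop_oracle_on_random_instances(self, rng):
        for _ in range(60):
            pat = random_pattern(rng, WINDOW, n_max=200)
            ps = find_colocalizing_pairs(pat, BAND)
            assert sorted(ps.pairs) == sorted(brute_pairs(pat, BAND))

    def test_pair_symmetry_counts(self, rng):
        pat = random_pattern(rng, WINDOW, n_max=100)
        ps = find_colocalizing_pairs(pat, BAND)
        assert ps.counts_a.sum() == ps.counts_b.sum() == len(ps.pairs)
        assert ps.n_col_a <= pat.n_a and ps.n_col_b <= pat.n_b


class TestFrequencyStage:
    def test_worked_example(self, example_stack):
        assert cc1_aggregate(example_stack) == pytest.approx((7.0, 4 / 7, 3 / 7))

    def test_single_label_image(self):
        pat = PointPattern("i", WINDOW, np.random.default_rng(1).random((5, 2)) * 100)
        assert cc1_aggregate([pat]) == (5.0, 1.0, 0.0)

    def test_two_image_hand_computation(self, rng):
        p1 = random_pattern(rng, WINDOW, n_max=2, n_min=2)
        p2 = PointPattern(
            "j", WINDOW, rng.random((6, 2)) * 100, rng.random((2, 2)) * 100
        )
        cc1_abs, rel_a, _ = cc1_aggregate([p1, p2])
        assert cc1_abs == pytest.approx((4 + 8) / 2)
        assert rel_a == pytest.approx((0.5 + 0.75) / 2)

    def test_empty_stack_is_an_error(self):
        with pytest.raises(ValueError):
            cc1_aggregate([])


class TestAggregatedColocalization:
    def test_worked_example(self, example_stack, example_band):
        assert cc2(example_stack, example_band) == pytest.approx((3 / 4, 2 / 3))

    def test_image_without_b_particles_scores_zero(self, rng):
        pat = PointPattern("i", WINDOW, rng.random((5, 2)) * 100)
        assert brute_cc2([pat], BAND)[0] == 0.0
        both = [pat, PointPattern("j", WINDOW, rng.random((2, 2)) * 100,
                                  rng.random((2, 2)) * 100)]
        cc2_a, _ = cc2(both, BAND)
        assert cc2_a <= 0.5  # the B-free image contributes a hard zero
        with pytest.raises(UndefinedCoefficientError):
            cc2([pat], BAND)  # cc2_b has no defined image at all

    def test_all_images_excluded_is_an_explicit_error(self):
        empty = PointPattern("i", WINDOW)
        with pytest.raises(UndefinedCoefficientError):
            cc2([empty], BAND)

    def test_matches_loop_oracle(self, rng):
        patterns = [random_pattern(rng, WINDOW, n_max=40, n_min=1) for _ in range(8)]
        got = cc2(patterns, BAND)
        assert got == pytest.approx(brute_cc2(patterns, BAND), abs=1e-14)

    def test_monotone_in_upper_bound(self, rng):
        patterns = [random_pattern(rng, WINDOW, n_max=60, n_min=5) for _ in range(6)]
        values = [cc2(patterns, DistanceBand(25.0, hi)) for hi in (50, 100, 200, 400)]
        for (a0, b0), (a1, b1) in zip(values, values[1:]):
            assert a1 >= a0 and b1 >= b0


class TestSummaryStage:
    def test_worked_example_quadruple(self, example_stack, example_band):
        cs = compute_coefficients(example_stack, example_band)
        agg = cs.aggregate
        assert agg["coloc_a"] == pytest.approx(3 / 7, abs=1e-15)
        assert agg["noncoloc_a"] == pytest.approx(1 / 7, abs=1e-15)
        assert agg["coloc_b"] == pytest.approx(2 / 7, abs=1e-15)
        assert agg["noncoloc_b"] == pytest.approx(1 / 7, abs=1e-15)

    def test_no_colocalization_reduces_to_frequency_stage(self):
        coloc_a, noncoloc_a, coloc_b, noncoloc_b = summary_coefficients(
            0.6, 0.4, 0.0, 0.0
        )
        assert (coloc_a, coloc_b) == (0.0, 0.0)
        assert (noncoloc_a, noncoloc_b) == (0.6, 0.4)

    @given(
        rel_a=st.floats(0.0, 1.0, allow_nan=False),
        c2a=st.floats(0.0, 1.0, allow_nan=False),
        c2b=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_complementary_inputs_always_sum_to_one(self, rel_a, c2a, c2b):
        four = summary_coefficients(rel_a, 1.0 - rel_a, c2a, c2b)
        assert sum(four) == pytest.approx(1.0, abs=1e-12)


class TestDensityStage:
    def test_worked_example(self, example_stack, example_band):
        assert cc3(example_stack, example_band) == pytest.approx((4 / 9, 1 / 2))

    def test_no_pairs_means_zero_density(self, rng):
        far = PointPattern("i", WINDOW, [[0.0, 0.0]], [[1900.0, 1900.0]])
        assert cc3([far], BAND) == (0.0, 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        patterns = [random_pattern(rng, WINDOW, n_max=40) for _ in range(20)]
        got = cc3(patterns, BAND)
        assert got == pytest.approx(brute_cc3(patterns, BAND), abs=1e-12)

    def test_unweighted_density_bounded_by_one_with_equality_iff_complete(self):
        # every colocalizing A paired with every B -> density exactly 1
        window = StudyWindow(1000.0, 1000.0)
        pts_a = [[500.0, 500.0], [530.0, 500.0]]
        pts_b = [[500.0, 530.0], [515.0, 470.0]]
        full = PointPattern("i", window, pts_a, pts_b)
        ba, ab = cc3([full], DistanceBand(0.0, 125.0))
        assert ba == 1.0 and ab == 1.0
        partial = PointPattern("i", window, pts_a, [[500.0, 530.0], [900.0, 900.0]])
        ba, _ = cc3([partial], DistanceBand(0.0, 125.0))
        assert ba < 1.0

    def test_edge_weighting_bounded_by_max_inverse_weight(self):
        # edge-hugging pattern: weighted density exceeds unweighted by < max(1/w)
        window = StudyWindow(500.0, 500.0)
        band = DistanceBand(0.0, 100.0)
        pts_a = [[5.0, 5.0], [5.0, 250.0]]
        pts_b = [[40.0, 5.0], [5.0, 280.0]]
        pat = PointPattern("i", window, pts_a, pts_b)
        plain, _ = cc3([pat], band)
        weighted, _ = cc3([pat], band, EdgeWeightSpec("annulus_fraction"))
        from emcoloc import annulus_window_fraction

        max_inv = 1.0 / annulus_window_fraction(np.array(pts_a), band, window).min()
        assert plain < weighted < plain * max_inv + 1e-12


class TestPipelineInvariances:
    def test_exchange_symmetry_swaps_every_coefficient(self, rng):
        patterns = [random_pattern(rng, WINDOW, n_max=40, n_min=1) for _ in range(5)]
        fwd = compute_coefficients(patterns, BAND).aggregate
        rev = compute_coefficients([p.swapped() for p in patterns], BAND).aggregate
        swap = {
            "cc1_rel_a": "cc1_rel_b", "cc2_a": "cc2_b", "coloc_a": "coloc_b",
            "noncoloc_a": "noncoloc_b", "cc3_ba": "cc3_ab",
        }
        assert fwd["cc1_abs"] == rev["cc1_abs"]
        for a, b in swap.items():
            assert fwd[a] == rev[b] and fwd[b] == rev[a]

    def test_particle_order_permutation_invariance(self, rng):
        pat = random_pattern(rng, WINDOW, n_max=30, n_min=5)
        perm = PointPattern(
            pat.image_id, pat.window,
            pat.points_a[rng.permutation(pat.n_a)],
            pat.points_b[rng.permutation(pat.n_b)],
        )
        assert compute_coefficients([pat], BAND).aggregate == pytest.approx(
            compute_coefficients([perm], BAND).aggregate
        )

    def test_common_scaling_leaves_all_coefficients_unchanged(self, rng):
        patterns = [random_pattern(rng, WINDOW, n_max=40, n_min=2) for _ in range(4)]
        factor = 3.7
        scaled = [p.scaled(factor) for p in patterns]
        band2 = DistanceBand(BAND.r_lo * factor, BAND.r_hi * factor)
        orig = compute_coefficients(patterns, BAND, EdgeWeightSpec("annulus_fraction"))
        resc = compute_coefficients(scaled, band2, EdgeWeightSpec("annulus_fraction"))
        for name in orig.aggregate:
            assert orig.aggregate[name] == pytest.approx(
                resc.aggregate[name], rel=1e-10
            )

    def test_relative_coefficients_stay_in_unit_interval(self, rng):
        patterns = [random_pattern(rng, WINDOW, n_max=50, n_min=1) for _ in range(10)]
        agg = compute_coefficients(patterns, BAND).aggregate
        for name, value in agg.items():
            if name != "cc1_abs":
                assert 0.0 <= value <= 1.0


class TestIdentities:
    def test_worked_example_residuals_vanish(self, example_stack, example_band):
        cs = compute_coefficients(example_stack, example_band)
        report = verify_identities(cs)
        assert report.exact and report.all_passed
        assert all(abs(r) <= 1e-12 for r in report.residuals.values())

    def test_injected_violation_is_flagged_not_raised(self, example_stack, example_band):
        cs = compute_coefficients(example_stack, example_band)
        cs.aggregate["coloc_a"] += 0.01
        report = verify_identities(cs)
        passed = report.passed
        assert not passed["summary_sum_to_one"]
        assert not passed["partition_a"]
        assert not passed["ratio_a"]
        assert passed["partition_b"] and passed["ratio_b"]
        assert not report.all_passed

    def test_report_marks_excluded_images_as_approximate(self):
        with_empty = [
            PointPattern("a", WINDOW, [[10.0, 10.0]], [[30.0, 10.0]]),
            PointPattern("b", WINDOW, [[10.0, 10.0]], np.empty((0, 2))),
        ]
        cs = compute_coefficients(with_empty, DistanceBand(0.0, 50.0))
        assert not verify_identities(cs).exact


class TestEstimatorApi:
    def test_fit_exposes_trailing_underscore_attributes(self, example_stack):
        est = ColocalizationCoefficients(band=(25.0, 125.0)).fit(example_stack)
        assert est.cc2_a_ == pytest.approx(0.75)
        assert est.n_images_ == 1
        assert est.identity_report().all_passed

    def test_get_set_params_roundtrip(self):
        est = ColocalizationCoefficients(band=(10.0, 20.0), edge_correction="none")
        params = est.get_params()
        clone = ColocalizationCoefficients().set_params(**params)
        assert clone.get_params() == params

    def test_rejects_non_pattern_input(self):
        with pytest.raises(TypeError):
            ColocalizationCoefficients().fit(np.zeros((3, 2)))
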