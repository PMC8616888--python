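"""Uncertainty scores, directionality, coverage, PWCC, heatmap correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from innuq.metrics import (
    directionality_accuracy,
    directionality_ratio,
    empirical_coverage,
    heatmap_change_correlation,
    mean_heatmap_change_correlation,
    pwcc,
    uncertainty_score,
)


class TestUncertaintyScore:
    def test_point_interval_is_zero(self):
        a = np.linspace(-1, 1, 5)
        np.testing.assert_array_equal(uncertainty_score(a, a), np.zeros(5))

    def test_width_and_translation_invariance(self, rng):
        lo = rng.standard_normal(10)
        hi = lo + rng.uniform(0, 3, 10)
        u = uncertainty_score(lo, hi)
        np.testing.assert_allclose(u, hi - lo)
        np.testing.assert_allclose(uncertainty_score(lo + 5.0, hi + 5.0), u)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_score(np.array([1.0]), np.array([0.0]))


class TestDirectionalityRatio:
    def test_midpoint_prediction_gives_one(self):
        dr = directionality_ratio(np.array([0.0]), np.array([2.0]),
                                  np.array([1.0]))
        assert dr[0] == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_example(self):
        dr = directionality_ratio(np.array([0.0]), np.array([3.0]),
                                  np.array([1.0]))
        assert dr[0] == pytest.approx(2.0, abs=1e-9)

    def test_boundary_prediction_undefined(self):
        dr = directionality_ratio(np.array([0.0]), np.array([1.0]),
                                  np.array([1.0]))
        assert np.isnan(dr[0])

    def test_prediction_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            directionality_ratio(np.array([0.0]), np.array([1.0]),
                                 np.array([1.5]))


class TestDirectionalityAccuracy:
    def test_targets_in_larger_part_give_da_one(self):
        lo = np.zeros(100)
        hi = np.full(100, 3.0)
        pred = np.full(100, 1.0)   # larger part is [1, 3]
        targets = np.full(100, 2.0)
        table = directionality_accuracy(lo, hi, pred, targets, n_bins=4)
        pop = table[table["count"] > 0]
        assert len(pop) > 0
        assert np.all(pop["da"] == 1.0)

    def test_uniform_targets_in_interval_match_width_fraction(self):
        """Uniformly placed targets fall in the larger part with probability
        equal to its width fraction (3/4 at DR = 3)."""
        r = np.random.default_rng(0)
        n = 200_000
        lo = np.zeros(n)
        hi = np.full(n, 4.0)
        pred = np.full(n, 1.0)  # DR = 3, larger part has 3/4 of the width
        targets = r.uniform(0.0, 4.0, n)
        table = directionality_accuracy(lo, hi, pred, targets,
                                        dr_bins=[1.0, 2.0, 3.5, 10.0])
        row = table.iloc[1]  # bin containing DR = 3
        assert row["count"] == n
        se = np.sqrt(0.75 * 0.25 / n)
        assert row["da"] == pytest.approx(0.75, abs=3 * se)

    def test_symmetric_intervals_with_symmetric_noise_are_chance(self):
        r = np.random.default_rng(1)
        n = 100_000
        pred = r.standard_normal(n)
        lo, hi = pred - 1.0, pred + 1.0001  # DR ~ 1, upper marginally larger
        targets = pred + r.normal(0, 0.3, n)
        table = directionality_accuracy(lo, hi, pred, targets, n_bins=1)
        da = table.loc[table["count"] > 0, "da"].iloc[0]
        assert da == pytest.approx(0.5, abs=0.01)

    def test_empty_bins_reported_as_missing(self):
        lo, hi, pred = np.zeros(4), np.full(4, 3.0), np.full(4, 1.0)
        targets = np.full(4, 2.0)
        table = directionality_accuracy(lo, hi, pred, targets,
                                        dr_bins=[1.0, 1.5, 2.5, 4.0])
        empty = table[table["count"] == 0]
        assert np.all(np.isnan(empty["da"]))
        assert table["freq"].sum() == pytest.approx(1.0)


class TestEmpiricalCoverage:
    def test_all_targets_inside_gives_one_for_any_lambda(self, rng):
        lo = np.zeros(10)
        hi = np.ones(10)
        x = rng.uniform(0.1, 0.9, 10)
        for lam in (0.5, 1.0, 2.0, 10.0):
            assert empirical_coverage(lo, hi, x, lam, 0.01) == 1.0

    def test_scalar_enlargement_hand_check(self):
        # x = 1.15 < hi + lam*beta = 1 + 0.2  -> covered
        got = empirical_coverage(np.array([0.0]), np.array([1.0]),
                                 np.array([1.15]), lam=2.0, beta=0.1)
        assert got == 1.0

    def test_nondecreasing_in_lambda(self, rng):
        lo = rng.standard_normal(500)
        hi = lo + rng.uniform(0, 0.5, 500)
        x = rng.standard_normal(500)
        lams = [0.5, 1.0, 2.0, 4.0, 8.0]
        covs = [empirical_coverage(lo, hi, x, lam, 0.2) for lam in lams]
        assert np.all(np.diff(covs) >= 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            empirical_coverage(np.zeros(2), np.ones(2), np.zeros(2), 0.0, 0.1)
        with pytest.raises(ValueError):
            empirical_coverage(np.zeros(2), np.ones(2), np.zeros(2), 1.0,
                               -0.1)


class TestPwcc:
    def test_four_component_hand_example(self):
        pred = np.array([0.0, 1.0, 0.0, -1.0])
        target = np.zeros(4)
        u = np.array([0.1, 0.9, 0.1, 0.9])
        # |err| = (0,1,0,1): corr with u is 1; MSE = 0.5 -> PWCC = 2
        assert pwcc(pred, target, u) == pytest.approx(2.0, abs=1e-9)

    def test_proportional_uncertainty_gives_inverse_mse(self, rng):
        pred = rng.standard_normal(64)
        target = rng.standard_normal(64)
        u = 3.0 * np.abs(pred - target)
        mse = float(np.mean((pred - target) ** 2))
        assert pwcc(pred, target, u) == pytest.approx(1.0 / mse, rel=1e-9)

    def test_constant_uncertainty_is_undefined(self, rng):
        pred = rng.standard_normal(10)
        assert np.isnan(pwcc(pred, np.zeros(10), np.full(10, 0.3)))

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            pwcc(np.array([1.0]), np.array([0.0]), np.array([1.0]))

    def test_permutation_invariance(self, rng):
        pred = rng.standard_normal(32)
        target = rng.standard_normal(32)
        u = rng.uniform(0, 1, 32)
        perm = rng.permutation(32)
        assert pwcc(pred[perm], target[perm], u[perm]) == \
            pytest.approx(pwcc(pred, target, u), rel=1e-12)

    def test_residual_scaling_law(self, rng):
        """Scaling residuals by c (with u co-scaled) scales PWCC by 1/c^2."""
        pred = rng.standard_normal(32)
        target = rng.standard_normal(32)
        u = rng.uniform(0, 1, 32)
        base = pwcc(pred, target, u)
        c = 2.5
        scaled = pwcc(target + c * (pred - target), target, c * u)
        assert scaled == pytest.approx(base / c**2, rel=1e-9)


class TestHeatmapChangeCorrelation:
    def test_no_change_is_undefined(self, rng):
        u = rng.uniform(0, 1, 16)
        assert np.isnan(heatmap_change_correlation(u, u, rng.uniform(0, 1, 16)))

    def test_exact_match_gives_one(self, rng):
        u_ref = rng.uniform(0, 1, 16)
        delta = rng.uniform(0, 1, 16)
        assert heatmap_change_correlation(u_ref, u_ref + delta, delta) == \
            pytest.approx(1.0, abs=1e-12)

    def test_noisy_mask_recovery_high_correlation(self):
        """Change map = mask; uncertainty change = mask + 10% noise."""
        r = np.random.default_rng(42)
        n = 512
        mask = np.zeros(n)
        mask[100:150] = 1.0
        du = mask + r.normal(0, 0.1, n)
        u_ref = np.zeros(n)
        got = heatmap_change_correlation(u_ref, np.abs(du), mask)
        assert got > 0.9

    def test_mean_over_samples_excludes_undefined(self, rng):
        u = rng.uniform(0, 1, (3, 8))
        du = rng.uniform(0.1, 1, (3, 8))
        mean, excluded = mean_heatmap_change_correlation(
            [u[0], u[1], u[2]], [u[0], u[1] + du[1], u[2] + du[2]],
            [du[0], du[1], du[2]])
        assert excluded == 1
        assert np.isfinite(mean)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_dr_always_at_least_one_where_defined(seed):
    r = np.random.default_rng(seed)
    lo = r.standard_normal(20)
    hi = lo + r.uniform(0, 2, 20)
    frac = r.uniform(0, 1, 20)
    pred = lo + frac * (hi - lo)
    dr = directionality_ratio(lo, hi, pred)
    defined = np.isfinite(dr)
    assert np.all(dr[defined] >= 1.0 - 1e-12)
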