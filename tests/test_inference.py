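"""Sliding-window statistics: permutation nulls, bootstrap CIs, Z-test."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from mifreq import (
    SlidingWindowPlan,
    TaskSessionParams,
    TrialWindowSet,
    accuracy_series,
    block_bootstrap_correlation,
    coupling_series,
    coupling_spectrum_series,
    dependent_correlation_ztest,
    permutation_max_threshold,
    run_session_analysis,
    simulate_task_session,
    sliding_trial_windows,
)

# small geometry used throughout: 0.3 s sub-windows of short trials
FAST_PLAN = SlidingWindowPlan(
    window_size=100, step=10, sub_window_starts=(0.0, 0.05, 0.1), sub_window_length=0.3
)


def _noise_session(n_trials, rng, fs=200.0, n_samples=80):
    x = TrialWindowSet(rng.standard_normal((n_trials, n_samples)), fs)
    y = TrialWindowSet(rng.standard_normal((n_trials, n_samples)), fs)
    return x, y


class TestSlidingWindows:
    def test_exact_window_count(self):
        plan = SlidingWindowPlan()
        assert sliding_trial_windows(100, plan) == [(0, 100)]
        assert sliding_trial_windows(130, plan) == [
            (0, 100), (10, 110), (20, 120), (30, 130)
        ]

    @pytest.mark.parametrize("n_trials", [100, 137, 401])
    def test_windows_stay_in_bounds(self, n_trials):
        plan = SlidingWindowPlan()
        for a, b in sliding_trial_windows(n_trials, plan):
            assert 0 <= a < b <= n_trials
            assert b - a == plan.window_size

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            sliding_trial_windows(50, SlidingWindowPlan())


class TestAccuracySeries:
    def test_all_correct(self):
        acc = accuracy_series(np.ones(120), SlidingWindowPlan())
        np.testing.assert_array_equal(acc, 1.0)

    def test_alternating_half(self):
        acc = accuracy_series(np.tile([0, 1], 60), SlidingWindowPlan())
        np.testing.assert_allclose(acc, 0.5)

    def test_aligned_with_window_count(self):
        plan = SlidingWindowPlan()
        acc = accuracy_series(np.zeros(173), plan)
        assert len(acc) == len(sliding_trial_windows(173, plan))


class TestCouplingSeries:
    def test_identical_channels_near_one(self, rng):
        x, _ = _noise_session(120, rng)
        series = coupling_series(x, x, FAST_PLAN, band=(2.0, 10.0))
        assert np.all(series > 0.99)

    def test_independent_channels_near_zero(self, rng):
        x, y = _noise_session(150, rng)
        series = coupling_series(x, y, FAST_PLAN, band=(2.0, 10.0))
        assert np.all(series < 0.15)

    def test_rising_profile_recovered(self):
        """The coupling series tracks the generating per-trial profile."""
        params = TaskSessionParams(n_trials=250, trial_length_s=0.5, seed=8)
        x, y, _ = simulate_task_session(params)
        plan = SlidingWindowPlan(
            window_size=100, step=10, sub_window_starts=(0.0, 0.05, 0.1),
            sub_window_length=0.3,
        )
        series = coupling_series(x, y, plan, band=params.band)
        profile_windows = [
            params.coupling_profile[a:b].mean()
            for a, b in sliding_trial_windows(250, plan)
        ]
        rho = spearmanr(series, profile_windows).statistic
        assert rho > 0.8

    def test_mif_post_method_runs(self, rng):
        x, y = _noise_session(120, rng)
        spec, freqs = coupling_spectrum_series(
            x, y, FAST_PLAN, band=(2.0, 10.0), method="mif_post"
        )
        assert spec.shape == (3, len(freqs))
        assert np.all(np.isfinite(spec))


class TestPermutationThreshold:
    def test_deterministic_under_seed(self, rng):
        x, y = _noise_session(110, rng)
        a = permutation_max_threshold(x, y, FAST_PLAN, (2.0, 10.0),
                                      n_permutations=150, seed=3)
        b = permutation_max_threshold(x, y, FAST_PLAN, (2.0, 10.0),
                                      n_permutations=150, seed=3)
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.null_max_samples, b.null_max_samples)

    def test_channel_symmetry_of_null(self, rng):
        """Permuting either channel's trial labels gives the same null."""
        x, y = _noise_session(110, rng)
        a = permutation_max_threshold(x, y, FAST_PLAN, (2.0, 10.0),
                                      n_permutations=1000, seed=4)
        b = permutation_max_threshold(y, x, FAST_PLAN, (2.0, 10.0),
                                      n_permutations=1000, seed=5)
        assert a.threshold == pytest.approx(b.threshold, rel=0.1)

    def test_strong_coupling_exceeds_threshold(self):
        params = TaskSessionParams(
            n_trials=150, trial_length_s=0.5,
            coupling_profile=np.full(150, 0.8), seed=9,
        )
        x, y, _ = simulate_task_session(params)
        plan = SlidingWindowPlan(
            window_size=150, step=10, sub_window_starts=(0.0, 0.05, 0.1),
            sub_window_length=0.3,
        )
        null = permutation_max_threshold(x, y, plan, params.band,
                                         n_permutations=200, seed=1)
        spec, _ = coupling_spectrum_series(x, y, plan, params.band)
        assert spec.max() > null.threshold

    def test_too_few_permutations_rejected(self, rng):
        x, y = _noise_session(110, rng)
        with pytest.raises(ValueError):
            permutation_max_threshold(x, y, FAST_PLAN, (2.0, 10.0), n_permutations=50)


class TestBlockBootstrap:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(40)
        res = block_bootstrap_correlation(x, x, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.significant

    def test_r_matches_pearson_exactly(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        res = block_bootstrap_correlation(x, y, n_bootstrap=50, seed=1)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            block_bootstrap_correlation(np.ones(20), rng.standard_normal(20))

    def test_default_block_length(self, rng):
        res = block_bootstrap_correlation(
            rng.standard_normal(27), rng.standard_normal(27), n_bootstrap=50, seed=2
        )
        assert res.block_length == math.ceil(27 ** (1 / 3))

    def test_coverage_on_independent_ar1_pairs(self):
        """The block bootstrap respects window-overlap autocorrelation.

        Percentile intervals for a correlation under-cover at short series;
        the block variant must stay near nominal and strictly beat the
        naive iid bootstrap on the same data.
        """
        def ar1(n, phi, r):
            e = r.standard_normal(n + 50)
            out = np.empty(n + 50)
            out[0] = e[0]
            for i in range(1, n + 50):
                out[i] = phi * out[i - 1] + e[i]
            return out[50:]

        rng = np.random.default_rng(77)
        cover_block = cover_iid = 0
        n_rep = 250
        for _ in range(n_rep):
            a, b = ar1(60, 0.5, rng), ar1(60, 0.5, rng)
            s1, s2 = (int(rng.integers(2**31)) for _ in range(2))
            rb = block_bootstrap_correlation(a, b, n_bootstrap=300, seed=s1)
            ri = block_bootstrap_correlation(a, b, block_length=1, n_bootstrap=300, seed=s2)
            cover_block += rb.ci_low <= 0.0 <= rb.ci_high
            cover_iid += ri.ci_low <= 0.0 <= ri.ci_high
        assert 0.85 <= cover_block / n_rep <= 0.99
        assert cover_block > cover_iid


class TestDependentCorrelationZ:
    def test_equal_correlations_give_zero(self):
        z, p = dependent_correlation_ztest(0.4, 0.4, 0.2, 50)
        assert z == 0.0 and p == 1.0

    def test_worked_example(self):
        """Frozen from an independent hand computation of the published
        formula for comparing two correlations sharing one variable."""
        z, p = dependent_correlation_ztest(0.63, 0.53, 0.68, 85)
        assert z == pytest.approx(1.453081, abs=1e-6)
        assert p == pytest.approx(0.146201, abs=1e-6)

    def test_antisymmetry(self):
        z1, p1 = dependent_correlation_ztest(0.63, 0.53, 0.68, 85)
        z2, p2 = dependent_correlation_ztest(0.53, 0.63, 0.68, 85)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_null_calibration_monte_carlo(self):
        """Under a trivariate normal with r1 = r2, the test's type-I error
        at alpha = 0.05 is near nominal (independent oracle check)."""
        cov = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.3], [0.5, 0.3, 1.0]])
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep, n = 2000, 120
        for _ in range(n_rep):
            z = rng.multivariate_normal(np.zeros(3), cov, n)
            r1 = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
            r2 = np.corrcoef(z[:, 0], z[:, 2])[0, 1]
            rb = np.corrcoef(z[:, 1], z[:, 2])[0, 1]
            _, p = dependent_correlation_ztest(r1, r2, rb, n)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dependent_correlation_ztest(1.0, 0.5, 0.2, 50)
        with pytest.raises(ValueError):
            dependent_correlation_ztest(0.5, 0.4, 0.3, 3)


class TestSessionAnalysis:
    def test_end_to_end_tables_and_gating(self):
        params = TaskSessionParams(n_trials=200, trial_length_s=0.5, seed=10)
        x, y, acc = simulate_task_session(params)
        plan = SlidingWindowPlan(
            window_size=100, step=10, sub_window_starts=(0.0, 0.05, 0.1),
            sub_window_length=0.3,
        )
        res = run_session_analysis(
            x, y, acc, plan, params.band, n_permutations=150, seed=11
        )
        assert len(res.windows) == len(sliding_trial_windows(200, plan))
        assert set(res.windows.columns) >= {
            "window_start_trial", "coupling", "accuracy", "passed_threshold"
        }
        assert res.correlation.r > 0.0
        # strong built-in coupling: every window passes the gate
        assert res.windows.passed_threshold.all()

    def test_accuracy_length_mismatch_rejected(self, rng):
        x = TrialWindowSet(rng.standard_normal((120, 80)), 200.0)
        with pytest.raises(ValueError, match="accuracy"):
            run_session_analysis(x, x, np.ones(119), FAST_PLAN, (2.0, 10.0),
                                 n_permutations=150)
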