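"""Kalman filter, RTS smoother and EM estimation."""

import numpy as np
import pytest

from conftest import dense_gaussian_oracle, random_toy_instance
from moodkf.inference import FitConfig, em_fit, kalman_filter, rts_smooth
from moodkf.model import ModelParameters, MoodSeries, build_grid, simulate_forward
from moodkf.synthetic import SamplingScheme, draw_ground_truth_params, nrmse, simulate_ema_dataset


def diag_params(n, a=0.9, sigma=0.1, gamma=0.5, h=None, mu0=None, p0=1.0):
    return ModelParameters(
        A=a * np.eye(n),
        h=np.zeros(n) if h is None else h,
        C=np.zeros((n, 0)),
        Sigma=sigma * np.eye(n),
        Gamma=gamma * np.eye(n),
        mu0=np.zeros(n) if mu0 is None else mu0,
        P0=p0 * np.eye(n),
    )


class TestKalmanFilter:
    def test_no_observations_gives_zero_loglik_and_prior_recursion(self):
        p = diag_params(2, a=0.9, h=np.array([0.2, -0.1]))
        series = MoodSeries("s", [0, 10], np.full((2, 2), np.nan))
        f = kalman_filter(p, series)
        assert f.loglik == 0.0
        m = p.mu0.copy()
        for t in range(1, 11):
            m = p.A @ m + p.h
        np.testing.assert_allclose(f.filtered_means[-1], m, atol=1e-12)

    def test_single_beep_conjugate_gaussian_update(self):
        # 1-D random walk with A=1, Sigma=0: posterior is the
        # precision-weighted combination of prior and observation.
        p0, gamma, mu0, y = 2.0, 0.5, 1.0, 3.0
        p = ModelParameters(
            A=np.eye(2),
            h=np.zeros(2),
            C=np.zeros((2, 0)),
            Sigma=np.zeros((2, 2)),
            Gamma=gamma * np.eye(2),
            mu0=np.array([mu0, 0.0]),
            P0=p0 * np.eye(2),
        )
        series = MoodSeries("s", [0], np.array([[y, np.nan]]))
        f = kalman_filter(p, series)
        expected = (mu0 / p0 + y / gamma) / (1 / p0 + 1 / gamma)
        np.testing.assert_allclose(f.filtered_means[0, 0], expected, atol=1e-12)

    def test_noiseless_observation_limit(self):
        p = diag_params(2, gamma=1e-10)
        y = np.array([[1.5, -2.0], [0.3, 0.7]])
        series = MoodSeries("s", [0, 40], y)
        f = kalman_filter(p, series)
        np.testing.assert_allclose(f.filtered_means[[0, 40]], y, atol=1e-6)

    def test_infinite_rating_rejected(self):
        p = diag_params(2)
        series = MoodSeries("s", [0, 5], np.array([[np.inf, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="non-finite"):
            kalman_filter(p, series)


class TestSmootherOracle:
    def test_t1_smoothed_equals_filtered(self):
        p = diag_params(2)
        series = MoodSeries("s", [0], np.array([[1.0, 2.0]]))
        f = kalman_filter(p, series)
        post = rts_smooth(p, f)
        np.testing.assert_array_equal(post.smoothed_means, f.filtered_means)

    def test_scalar_chain_with_gap_matches_joint_conditioning(self):
        # N=1 active item, T=4, beeps at t in {0, 3}
        p = diag_params(2, a=0.7, sigma=0.3, gamma=0.4)
        ratings = np.array([[1.0, np.nan], [-0.5, np.nan]])
        series = MoodSeries("s", [0, 3], ratings)
        grid = build_grid(series)
        m, c, l1, ll = dense_gaussian_oracle(p, series, grid)
        post = rts_smooth(p, kalman_filter(p, series, grid))
        np.testing.assert_allclose(post.smoothed_means, m, atol=1e-8)
        np.testing.assert_allclose(post.smoothed_covs, c, atol=1e-8)
        np.testing.assert_allclose(post.lag1_covs, l1, atol=1e-8)
        assert abs(post.loglik - ll) < 1e-8

    def test_bivariate_dense_beeps_including_lag_one(self, rng):
        a = np.array([[0.8, 0.1], [-0.2, 0.7]])
        p = ModelParameters(
            A=a,
            h=np.array([0.1, -0.3]),
            C=np.zeros((2, 0)),
            Sigma=np.diag([0.3, 0.6]),
            Gamma=np.diag([0.4, 0.8]),
            mu0=np.array([0.5, -0.5]),
            P0=np.diag([1.0, 2.0]),
        )
        series = MoodSeries("s", [0, 1, 2], rng.standard_normal((3, 2)))
        grid = build_grid(series)
        m, c, l1, ll = dense_gaussian_oracle(p, series, grid)
        post = rts_smooth(p, kalman_filter(p, series, grid))
        np.testing.assert_allclose(post.smoothed_means, m, atol=1e-8)
        np.testing.assert_allclose(post.lag1_covs, l1, atol=1e-8)
        assert abs(post.loglik - ll) < 1e-8

    def test_random_toys_match_oracle(self, rng):
        for _ in range(15):
            params, series, grid = random_toy_instance(rng)
            m, c, l1, ll = dense_gaussian_oracle(params, series, grid)
            post = rts_smooth(params, kalman_filter(params, series, grid))
            np.testing.assert_allclose(post.smoothed_means, m, atol=1e-8)
            np.testing.assert_allclose(post.smoothed_covs, c, atol=1e-8)
            if l1.size:
                np.testing.assert_allclose(post.lag1_covs, l1, atol=1e-8)
            assert abs(post.loglik - ll) < 1e-8


class TestEmFit:
    def test_near_noiseless_dynamics_recovery(self):
        truth = draw_ground_truth_params(
            2, noise_var=0.01, seed=11, process_var=1e-3
        )
        bundle = simulate_ema_dataset(truth, SamplingScheme(n_days=6), seed=12)
        fit = em_fit(bundle.observed, FitConfig(max_iter=40, tol=1e-7), seed=13)
        assert nrmse(truth.A, fit.params.A) <= 0.05

    def test_loglik_trace_non_decreasing(self):
        truth = draw_ground_truth_params(2, noise_var=1.0, seed=21)
        bundle = simulate_ema_dataset(truth, SamplingScheme(n_days=2), seed=22)
        fit = em_fit(bundle.observed, FitConfig(max_iter=25), seed=23)
        diffs = np.diff(fit.loglik_trace)
        scale = np.maximum(1.0, np.abs(fit.loglik_trace[:-1]))
        assert np.all(diffs >= -1e-6 * scale)

    def test_free_input_weights_stay_near_zero_when_truth_has_none(self):
        # inputs recorded but C = 0 in the generator
        truth = draw_ground_truth_params(
            2, n_inputs=2, noise_var=0.5, seed=31, input_density=0.0
        )
        assert not truth.C.any()
        bundle = simulate_ema_dataset(truth, SamplingScheme(n_days=6), seed=32)
        fit = em_fit(bundle.observed, FitConfig(max_iter=30, free_C=True), seed=33)
        assert np.max(np.abs(fit.params.C)) < 0.5

    def test_item_permutation_leaves_loglik_unchanged(self):
        truth = draw_ground_truth_params(3, noise_var=0.5, seed=41)
        bundle = simulate_ema_dataset(truth, SamplingScheme(n_days=2), seed=42)
        s = bundle.observed
        perm = [2, 0, 1]
        s_perm = MoodSeries(
            "perm", s.beep_times, s.ratings[:, perm], item_names=[s.item_names[i] for i in perm]
        )
        cfg = FitConfig(max_iter=10, init_jitter=0.0)
        ll = em_fit(s, cfg, seed=5).loglik_trace
        ll_perm = em_fit(s_perm, cfg, seed=5).loglik_trace
        np.testing.assert_allclose(ll, ll_perm, rtol=1e-8)

    def test_all_missing_item_is_named_in_error(self):
        ratings = np.array([[1.0, np.nan], [2.0, np.nan], [1.5, np.nan]])
        s = MoodSeries("s", [0, 60, 120], ratings, item_names=["cheerful", "sad"])
        with pytest.raises(ValueError, match="sad"):
            em_fit(s)

    def test_too_few_beeps_rejected(self):
        s = MoodSeries("s", [0], np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="at least 2"):
            em_fit(s)

    def test_deterministic_given_seed(self):
        truth = draw_ground_truth_params(2, noise_var=1.0, seed=51)
        bundle = simulate_ema_dataset(truth, SamplingScheme(n_days=2), seed=52)
        f1 = em_fit(bundle.observed, FitConfig(max_iter=5), seed=9)
        f2 = em_fit(bundle.observed, FitConfig(max_iter=5), seed=9)
        np.testing.assert_array_equal(f1.params.A, f2.params.A)
        np.testing.assert_array_equal(f1.loglik_trace, f2.loglik_trace)

    def test_smoothed_mean_tracks_observation_when_noise_tiny(self):
        p = diag_params(2, a=0.99, sigma=0.05, gamma=1e-8)
        series = MoodSeries("s", [0, 30, 60], np.array([[1.0, 0.5], [0.8, 0.4], [0.9, 0.1]]))
        post = rts_smooth(p, kalman_filter(p, series))
        grid = build_grid(series)
        np.testing.assert_allclose(
            post.smoothed_means[grid.obs_index], series.ratings, atol=1e-4
        )
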