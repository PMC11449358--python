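"""Shared fixtures and independent oracles.

The central oracle builds the full joint Gaussian over every latent
state on the grid and conditions it on the observed ratings by dense
linear algebra — an implementation-independent reference for the Kalman
filter / RTS smoother moments and the marginal log-likelihood.
"""

from __future__ import annotations

import numpy as np
import pytest

from moodkf.model import LatentGrid, ModelParameters, MoodSeries, build_grid


def dense_gaussian_oracle(params: ModelParameters, series: MoodSeries, grid: LatentGrid):
    """Exact smoothed moments and loglik by brute-force joint conditioning.

    Returns (means (T,N), covs (T,N,N), lag1 (T-1,N,N), loglik) where
    lag1[t] = Cov(z_{t+1}, z_t | observations).
    """
    T, N = grid.n_steps, params.n_items
    A, h, C = params.A, params.h, params.C
    u = grid.input_at_grid
    k = params.n_inputs

    mu = np.zeros((T, N))
    mu[0] = params.mu0 + (C @ u[0] if k else 0.0)
    for t in range(1, T):
        mu[t] = A @ mu[t - 1] + h + (C @ u[t] if k else 0.0)

    K = np.zeros((T, T, N, N))
    K[0, 0] = params.P0
    for t in range(1, T):
        K[t, t] = A @ K[t - 1, t - 1] @ A.T + params.Sigma
    for s in range(T):
        for t in range(s + 1, T):
            K[t, s] = A @ K[t - 1, s]
            K[s, t] = K[t, s].T
    big = K.transpose(0, 2, 1, 3).reshape(T * N, T * N)
    mu_flat = mu.reshape(-1)

    obs_idx, y = [], []
    for j, gi in enumerate(grid.obs_index):
        for i in range(N):
            if np.isfinite(series.ratings[j, i]):
                obs_idx.append(gi * N + i)
                y.append(series.ratings[j, i])
    obs_idx = np.asarray(obs_idx, dtype=int)
    y = np.asarray(y)

    if obs_idx.size == 0:
        post_mean, post_cov, ll = mu_flat, big, 0.0
    else:
        gam = np.diag(params.Gamma)[obs_idx % N]
        cov_xx = big[np.ix_(obs_idx, obs_idx)] + np.diag(gam)
        cross = big[:, obs_idx]
        sol = np.linalg.solve(cov_xx, y - mu_flat[obs_idx])
        post_mean = mu_flat + cross @ sol
        post_cov = big - cross @ np.linalg.solve(cov_xx, cross.T)
        sign, logdet = np.linalg.slogdet(cov_xx)
        assert sign > 0
        ll = -0.5 * (
            obs_idx.size * np.log(2 * np.pi)
            + logdet
            + (y - mu_flat[obs_idx]) @ sol
        )

    means = post_mean.reshape(T, N)
    covs = np.empty((T, N, N))
    lag1 = np.empty((max(T - 1, 0), N, N))
    for t in range(T):
        covs[t] = post_cov[t * N : (t + 1) * N, t * N : (t + 1) * N]
        if t < T - 1:
            lag1[t] = post_cov[(t + 1) * N : (t + 2) * N, t * N : (t + 1) * N]
    return means, covs, lag1, float(ll)


def random_toy_instance(rng: np.random.Generator, n_max: int = 2, t_max: int = 6):
    """Random small state-space instance with random missingness."""
    n = int(rng.integers(1, n_max + 1))
    T = int(rng.integers(2, t_max + 1))
    n_beeps = int(rng.integers(1, T + 1))
    beeps = np.sort(rng.choice(T, size=n_beeps, replace=False))
    if beeps[0] != 0:
        beeps = beeps - beeps[0]
    a = 0.5 * rng.standard_normal((n, n)) + 0.3 * np.eye(n)
    a = a / max(1.0, 1.2 * np.max(np.abs(np.linalg.eigvals(a))))
    k = int(rng.integers(0, 2))
    params = ModelParameters(
        A=a,
        h=0.3 * rng.standard_normal(n),
        C=rng.standard_normal((n, k)),
        Sigma=np.diag(rng.uniform(0.2, 1.5, n)),
        Gamma=np.diag(rng.uniform(0.2, 1.5, n)),
        mu0=rng.standard_normal(n),
        P0=np.diag(rng.uniform(0.5, 1.5, n)),
    )
    ratings = rng.standard_normal((n_beeps, n))
    miss = rng.random((n_beeps, n)) < 0.3
    ratings[miss] = np.nan
    inputs = None
    if k:
        inputs = (rng.random((n_beeps, k)) < 0.5).astype(float)
    if n == 1:  # MoodSeries requires >= 2 items; widen then mask one out
        ratings = np.column_stack([ratings, np.full(n_beeps, np.nan)])
        params_wide = ModelParameters(
            A=np.block([[params.A, np.zeros((1, 1))], [np.zeros((1, 1)), 0.5 * np.eye(1)]]),
            h=np.concatenate([params.h, [0.0]]),
            C=np.vstack([params.C, np.zeros((1, k))]),
            Sigma=np.diag(np.append(np.diag(params.Sigma), 1.0)),
            Gamma=np.diag(np.append(np.diag(params.Gamma), 1.0)),
            mu0=np.append(params.mu0, 0.0),
            P0=np.diag(np.append(np.diag(params.P0), 1.0)),
        )
        params = params_wide
    series = MoodSeries(
        subject_id="toy", beep_times=beeps, ratings=ratings, inputs=inputs
    )
    return params, series, build_grid(series)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240923)
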