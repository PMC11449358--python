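"""Exact E-step (Kalman filter + RTS smoother) and EM parameter estimation.

The latent process runs on the full one-minute grid, so between beeps
the filter only predicts; at a beep it updates with whichever items were
answered (individual missing items are skipped).  The M-step maximizes
the expected complete-data log-likelihood in closed form: ``A``, ``h``
(and ``C`` when inputs are modelled) come from a joint linear regression
of ``z_t`` on ``[z_{t-1}, 1, u_t]`` under the smoothed moments; ``Sigma``
and ``Gamma`` are the expected residual variances projected to diagonal;
``mu0`` absorbs the first-state term.  Because the per-minute ``A`` is
estimated directly, fractional matrix powers are needed only when
reporting at other timescales, never inside EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kalman
from .model import LatentGrid, ModelParameters, MoodSeries, build_grid

__all__ = [
    "KalmanFilterResult",
    "LatentPosterior",
    "FitConfig",
    "FitResult",
    "kalman_filter",
    "rts_smooth",
    "em_fit",
]


@dataclass
class KalmanFilterResult:
    """Forward-pass output: predicted and filtered moments plus loglik."""

    pred_means: np.ndarray
    pred_covs: np.ndarray
    filtered_means: np.ndarray
    filtered_covs: np.ndarray
    loglik: float


@dataclass
class LatentPosterior:
    """Smoothed posterior over the latent trajectory on the minute grid."""

    smoothed_means: np.ndarray
    smoothed_covs: np.ndarray
    lag1_covs: np.ndarray
    filtered_means: np.ndarray
    filtered_covs: np.ndarray
    loglik: float


@dataclass
class FitConfig:
    """EM settings.

    free_C: None means "estimate C iff the series has inputs".
    """

    max_iter: int = 200
    tol: float = 1e-6
    free_C: bool | None = None
    free_mu0: bool = True
    free_P0: bool = False
    multi_start: int = 1
    init_diag: float = 0.99
    init_jitter: float = 1e-3
    init_split: float = 0.5
    var_floor: float = 1e-10
    stability_margin: float = 1e-6
    center_items: bool = False


@dataclass
class FitResult:
    params: ModelParameters
    posterior: LatentPosterior
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    config_echo: dict = field(default_factory=dict)


def _grid_observations(series: MoodSeries, grid: LatentGrid):
    """Scatter beeps onto the grid: (T, N) values + boolean mask."""
    if np.any(np.isinf(series.ratings)):
        raise ValueError(f"subject {series.subject_id!r}: non-finite ratings")
    t_grid, n = grid.n_steps, series.n_items
    y = np.zeros((t_grid, n))
    mask = np.zeros((t_grid, n), dtype=bool)
    obs = np.isfinite(series.ratings)
    y[grid.obs_index] = np.where(obs, series.ratings, 0.0)
    mask[grid.obs_index] = obs
    return y, mask


def kalman_filter(
    params: ModelParameters, series: MoodSeries, grid: LatentGrid | None = None
) -> KalmanFilterResult:
    """Forward Kalman pass on the minute grid.

    Predicts every minute with ``A, h, C u_t``; updates only at beep rows
    and only with the non-missing items there.  ``loglik`` is the exact
    marginal log-likelihood of the observed entries.
    """
    grid = grid or build_grid(series)
    y, mask = _grid_observations(series, grid)
    if np.any(np.diag(params.Gamma) <= 0) and mask.any():
        raise ValueError("Gamma diagonal must be strictly positive for filtering")
    try:
        pm, pP, fm, fP, ll = _kalman.filter_pass(
            params.A,
            params.h,
            np.ascontiguousarray(params.C),
            params.Sigma,
            np.ascontiguousarray(np.diag(params.Gamma)),
            params.mu0,
            params.P0,
            np.ascontiguousarray(grid.input_at_grid),
            y,
            mask,
        )
    except np.linalg.LinAlgError as e:  # pragma: no cover - numerical guard
        raise np.linalg.LinAlgError(
            f"singular innovation covariance while filtering subject "
            f"{series.subject_id!r}"
        ) from e
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite log-likelihood for subject {series.subject_id!r}"
        )
    return KalmanFilterResult(pm, pP, fm, fP, float(ll))


def rts_smooth(params: ModelParameters, filt: KalmanFilterResult) -> LatentPosterior:
    """Backward (Rauch–Tung–Striebel) pass producing the smoothed posterior.

    Also returns the lag-one cross-covariances Cov(z_{t+1}, z_t | x)
    required by the M-step.  The last smoothed state equals the last
    filtered state.
    """
    sm, sP, lag1 = _kalman.smooth_pass(
        params.A,
        filt.pred_means,
        filt.pred_covs,
        filt.filtered_means,
        filt.filtered_covs,
    )
    return LatentPosterior(
        smoothed_means=sm,
        smoothed_covs=sP,
        lag1_covs=lag1,
        filtered_means=filt.filtered_means,
        filtered_covs=filt.filtered_covs,
        loglik=filt.loglik,
    )


def _initial_params(
    series: MoodSeries, grid: LatentGrid, config: FitConfig, rng: np.random.Generator
) -> ModelParameters:
    n, k = series.n_items, series.n_inputs
    a = config.init_diag * np.eye(n) + config.init_jitter * rng.standard_normal((n, n))
    item_var = np.nanvar(series.ratings, axis=0)
    item_var = np.where(np.isfinite(item_var) & (item_var > 0), item_var, 1.0)
    item_mean = np.nanmean(series.ratings, axis=0)
    mu0 = np.where(np.isfinite(series.ratings[0]), series.ratings[0], item_mean)
    mu0 = np.where(np.isfinite(mu0), mu0, 0.0)
    # moment-matched split of the observed variance: a fraction is
    # attributed to the stationary latent process (variance
    # sigma/(1 - a^2) under the slow-diagonal init), the rest to
    # observation noise -- EM then refines both from a consistent start
    split = config.init_split
    latent_var = split * item_var
    sigma0 = np.clip(latent_var * (1.0 - config.init_diag**2), 1e-8, None)
    gamma0 = np.clip((1.0 - split) * item_var, 1e-6, None)
    return ModelParameters(
        A=a,
        h=np.zeros(n),
        C=np.zeros((n, k)),
        Sigma=np.diag(sigma0),
        Gamma=np.diag(gamma0),
        mu0=mu0,
        P0=np.eye(n),
    )


def _project_stable(a: np.ndarray, margin: float) -> tuple[np.ndarray, bool]:
    """Shrink eigenvalue magnitudes to 1-margin if the spectral radius >= 1."""
    w = np.linalg.eigvals(a)
    if np.max(np.abs(w)) < 1.0:
        return a, False
    w, v = np.linalg.eig(a)
    mags = np.abs(w)
    cap = 1.0 - margin
    scale = np.where(mags > cap, cap / mags, 1.0)
    a_new = (v @ np.diag(w * scale) @ np.linalg.inv(v)).real
    return a_new, True


def _m_step(
    params: ModelParameters,
    post: LatentPosterior,
    grid: LatentGrid,
    y: np.ndarray,
    mask: np.ndarray,
    series: MoodSeries,
    config: FitConfig,
    free_c: bool,
) -> tuple[ModelParameters, bool]:
    n = params.n_items
    t_grid = grid.n_steps
    u = np.ascontiguousarray(grid.input_at_grid)
    S11, S10, S00, s1, s0, Z1U, Z0U, Suu, su = _kalman.transition_suffstats(
        post.smoothed_means, post.smoothed_covs, post.lag1_covs, u
    )
    n_trans = t_grid - 1
    projected = False

    if n_trans >= 1:
        if free_c and params.n_inputs > 0:
            k = params.n_inputs
            d = n + 1 + k
            G = np.empty((d, d))
            G[:n, :n] = S00
            G[:n, n] = s0
            G[n, :n] = s0
            G[n, n] = n_trans
            G[:n, n + 1 :] = Z0U
            G[n + 1 :, :n] = Z0U.T
            G[n, n + 1 :] = su
            G[n + 1 :, n] = su
            G[n + 1 :, n + 1 :] = Suu
            W = np.concatenate([S10, s1[:, None], Z1U], axis=1)
            theta = np.linalg.solve(
                G + 1e-9 * np.eye(d) * max(1.0, np.trace(G) / d), W.T
            ).T
            a_new = theta[:, :n]
            h_new = theta[:, n]
            c_new = theta[:, n + 1 :]
            resid = S11 - theta @ W.T - W @ theta.T + theta @ G @ theta.T
        else:
            c_new = params.C
            k = params.n_inputs
            if k:
                W = np.concatenate(
                    [S10 - c_new @ Z0U.T, (s1 - c_new @ su)[:, None]], axis=1
                )
                R11 = S11 - Z1U @ c_new.T - c_new @ Z1U.T + c_new @ Suu @ c_new.T
            else:
                W = np.concatenate([S10, s1[:, None]], axis=1)
                R11 = S11
            d = n + 1
            G = np.empty((d, d))
            G[:n, :n] = S00
            G[:n, n] = s0
            G[n, :n] = s0
            G[n, n] = n_trans
            theta = np.linalg.solve(
                G + 1e-9 * np.eye(d) * max(1.0, np.trace(G) / d), W.T
            ).T
            a_new = theta[:, :n]
            h_new = theta[:, n]
            resid = R11 - theta @ W.T - W @ theta.T + theta @ G @ theta.T
        sigma_diag = np.clip(np.diag(resid) / n_trans, config.var_floor, None)
        a_new, projected = _project_stable(a_new, config.stability_margin)
    else:  # single-point grid: transitions carry no information
        a_new, h_new, c_new = params.A, params.h, params.C
        sigma_diag = np.diag(params.Sigma)

    # Gamma: expected squared observation residual per item, observed beeps only
    gamma_diag = np.diag(params.Gamma).copy()
    sm = post.smoothed_means
    sv = np.einsum("tii->ti", post.smoothed_covs)
    for i in range(n):
        rows = mask[:, i]
        if rows.any():
            resid2 = (y[rows, i] - sm[rows, i]) ** 2 + sv[rows, i]
            gamma_diag[i] = max(float(np.mean(resid2)), config.var_floor)

    mu0_new = params.mu0
    if config.free_mu0:
        u0 = grid.input_at_grid[0]
        mu0_new = sm[0] - (c_new @ u0 if params.n_inputs else 0.0)
    p0_new = params.P0
    if config.free_P0:
        dev = sm[0] - mu0_new - (c_new @ grid.input_at_grid[0] if params.n_inputs else 0.0)
        p0_new = post.smoothed_covs[0] + np.outer(dev, dev)
        p0_new = 0.5 * (p0_new + p0_new.T) + config.var_floor * np.eye(n)

    new = ModelParameters(
        A=a_new,
        h=h_new,
        C=c_new,
        Sigma=np.diag(sigma_diag),
        Gamma=np.diag(gamma_diag),
        mu0=mu0_new,
        P0=p0_new,
    )
    return new, projected


def _em_single(
    series: MoodSeries,
    grid: LatentGrid,
    config: FitConfig,
    rng: np.random.Generator,
) -> FitResult:
    params = _initial_params(series, grid, config, rng)
    y, mask = _grid_observations(series, grid)
    free_c = series.n_inputs > 0 if config.free_C is None else config.free_C
    trace: list[float] = []
    converged = False
    projected_last = False
    post = None
    for it in range(config.max_iter + 1):
        filt = kalman_filter(params, series, grid)
        post = rts_smooth(params, filt)
        ll = filt.loglik
        if trace:
            prev = trace[-1]
            scale = max(1.0, abs(prev))
            if ll < prev - 1e-6 * scale:
                if projected_last:
                    warnings.warn(
                        "log-likelihood decreased after a stability/variance "
                        "projection; stopping EM at the previous parameters",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    break
                raise RuntimeError(
                    f"EM log-likelihood decreased ({prev:.6f} -> {ll:.6f}) "
                    f"at iteration {it}: implementation bug sentinel"
                )
            trace.append(ll)
            if (ll - prev) / scale < config.tol:
                converged = True
                break
        else:
            trace.append(ll)
        if it == config.max_iter:
            break
        params, projected_last = _m_step(
            params, post, grid, y, mask, series, config, free_c
        )
    return FitResult(
        params=params,
        posterior=post,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace) - 1,
        config_echo=asdict(config),
    )


def em_fit(series: MoodSeries, config: FitConfig | None = None, seed: int = 0) -> FitResult:
    """Fit the per-minute state-space model to one individual's series by EM.

    Alternates the exact E-step (filter + smoother on the minute grid)
    with closed-form M-steps until the marginal log-likelihood improves
    by less than ``config.tol`` (relative) or ``config.max_iter`` is
    reached.  Deterministic given ``seed`` (which drives initialization
    jitter and multi-start).
    """
    config = config or FitConfig()
    n_obs_per_beep = np.sum(np.isfinite(series.ratings), axis=1)
    if np.sum(n_obs_per_beep > 0) < 2:
        raise ValueError("need at least 2 beeps with at least one observed item")
    all_missing = ~np.any(np.isfinite(series.ratings), axis=0)
    if np.any(all_missing):
        bad = series.item_names[int(np.where(all_missing)[0][0])]
        raise ValueError(f"item {bad!r} has no observed values")
    if config.center_items:
        centered = series.ratings - np.nanmean(series.ratings, axis=0)
        series = MoodSeries(
            subject_id=series.subject_id,
            beep_times=series.beep_times,
            ratings=centered,
            inputs=series.inputs,
            item_names=series.item_names,
            input_names=series.input_names,
            valence_signs=series.valence_signs,
        )
    grid = build_grid(series)
    root = np.random.SeedSequence(seed)
    starts = max(1, config.multi_start)
    best: FitResult | None = None
    for child in root.spawn(starts):
        fit = _em_single(series, grid, config, np.random.default_rng(child))
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    return best
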