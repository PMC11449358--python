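"""Affect-dynamics summary features, the VAR(1) baseline, and surrogate checks.

The classical EMA summary statistics — per-item mean and variance,
item-pair covariance, inertia (lag-1 temporal autocorrelation in beep
order) and instability (RMSSD, root mean square of successive
differences) — are computed directly from observed beeps.  The VAR(1)
baseline regresses each beep on the previous one while ignoring gap
lengths, which is exactly the simplification the state-space model
avoids.  The surrogate check simulates series from fitted parameters on
the empirical beep schedule and correlates surrogate features with
empirical ones across individuals, for the state-space route and the
VAR route in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult
from .model import ModelParameters, MoodSeries, build_grid, simulate_forward

__all__ = [
    "FeatureSet",
    "VarFit",
    "compute_features",
    "var_fit",
    "var_simulate",
    "surrogate_feature_check",
]


@dataclass
class FeatureSet:
    mean: np.ndarray
    variance: np.ndarray
    covariance: np.ndarray
    autocorr_lag1: np.ndarray
    autocorr_by_lag: np.ndarray  # (max_lag, N); NaN where undefined
    rmssd: np.ndarray


@dataclass
class VarFit:
    coef: np.ndarray
    intercept: np.ndarray
    resid_cov: np.ndarray
    n_pairs: int


def _lag_corr(x: np.ndarray, k: int) -> float:
    """Autocorrelation at beep-lag k over pairs with both values observed."""
    a, b = x[:-k], x[k:]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    a, b = a[ok], b[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compute_features(series: MoodSeries, max_lag: int = 5) -> FeatureSet:
    """Summary features over beeps, missing entries pairwise-deleted.

    Autocorrelations are computed in beep order (consecutive-beep pairs k
    apart), deliberately ignoring gap heterogeneity — the conventional
    EMA definition of inertia.  Undefined features (constant or entirely
    missing items) are NaN.
    """
    x = series.ratings
    n = series.n_items
    df = pd.DataFrame(x)
    mean = df.mean(skipna=True).to_numpy()
    variance = df.var(ddof=1, skipna=True).to_numpy()
    covariance = df.cov().to_numpy()
    ac = np.full((max_lag, n), np.nan)
    for k in range(1, max_lag + 1):
        if x.shape[0] > k:
            ac[k - 1] = [_lag_corr(x[:, i], k) for i in range(n)]
    diffs = np.diff(x, axis=0)
    rmssd = np.full(n, np.nan)
    for i in range(n):
        d = diffs[:, i][np.isfinite(diffs[:, i])]
        if d.size:
            rmssd[i] = float(np.sqrt(np.mean(d**2)))
    return FeatureSet(
        mean=mean,
        variance=variance,
        covariance=covariance,
        autocorr_lag1=ac[0].copy(),
        autocorr_by_lag=ac,
        rmssd=rmssd,
    )


def _consecutive_pairs(series: MoodSeries, within_day: bool = False):
    x = series.ratings
    prev, curr = x[:-1], x[1:]
    ok = np.all(np.isfinite(prev), axis=1) & np.all(np.isfinite(curr), axis=1)
    if within_day:
        days = series.beep_times // 1440
        ok &= days[:-1] == days[1:]
    return prev[ok], curr[ok]


def var_fit(series: MoodSeries, within_day: bool = False) -> VarFit:
    """VAR(1) by per-equation OLS on consecutive beeps, gaps ignored.

    Pairs with any missing entry are dropped; overnight transitions are
    included unless ``within_day``.
    """
    prev, curr = _consecutive_pairs(series, within_day)
    n = series.n_items
    if prev.shape[0] < n + 1:
        raise ValueError(
            f"need at least {n + 1} complete consecutive-beep pairs, got {prev.shape[0]}"
        )
    design = np.concatenate([prev, np.ones((prev.shape[0], 1))], axis=1)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient VAR design matrix")
    theta, *_ = np.linalg.lstsq(design, curr, rcond=None)
    coef = theta[:-1].T
    intercept = theta[-1]
    resid = curr - design @ theta
    dof = max(prev.shape[0] - (n + 1), 1)
    resid_cov = resid.T @ resid / dof
    return VarFit(coef=coef, intercept=intercept, resid_cov=resid_cov, n_pairs=prev.shape[0])


def var_simulate(fit: VarFit, series: MoodSeries, rng: np.random.Generator) -> MoodSeries:
    """Simulate a surrogate series from a VAR(1) fit on the same beep slots.

    One discrete step per beep, regardless of the actual gaps — the VAR
    assumption.  Starts from the first observed beep (missing entries
    replaced by item means).
    """
    n = series.n_items
    tau = series.n_beeps
    chol = np.linalg.cholesky(
        fit.resid_cov + 1e-12 * np.eye(n) * max(1.0, np.trace(fit.resid_cov) / n)
    )
    x = np.empty((tau, n))
    mean0 = np.nanmean(series.ratings, axis=0)
    start = np.where(np.isfinite(series.ratings[0]), series.ratings[0], mean0)
    x[0] = np.where(np.isfinite(start), start, 0.0)
    for t in range(1, tau):
        x[t] = fit.coef @ x[t - 1] + fit.intercept + chol @ rng.standard_normal(n)
    return MoodSeries(
        subject_id=f"{series.subject_id}:var-surrogate",
        beep_times=series.beep_times,
        ratings=x,
        inputs=series.inputs,
        item_names=series.item_names,
        input_names=series.input_names,
        valence_signs=series.valence_signs,
    )


def _kalman_surrogate(
    params: ModelParameters, series: MoodSeries, rng: np.random.Generator
) -> MoodSeries:
    grid = build_grid(series)
    _, sim = simulate_forward(params, grid, rng, subject_id=f"{series.subject_id}:kf-surrogate")
    sim.ratings[~np.isfinite(series.ratings)] = np.nan  # mirror empirical missingness
    return sim


_FEATURES = ("mean", "variance", "covariance", "autocorr_lag1", "rmssd")


def _feature_vectors(fs: FeatureSet) -> dict[str, np.ndarray]:
    n = fs.mean.size
    iu = np.triu_indices(n, k=1)
    return {
        "mean": fs.mean,
        "variance": fs.variance,
        "covariance": fs.covariance[iu],
        "autocorr_lag1": fs.autocorr_lag1,
        "rmssd": fs.rmssd,
    }


def surrogate_feature_check(
    population: list[MoodSeries],
    fits: list[FitResult | ModelParameters],
    n_surrogates: int = 5,
    seed: int = 0,
    max_lag: int = 5,
) -> pd.DataFrame:
    """Cross-individual empirical-vs-surrogate feature correlations.

    For every individual, features of ``n_surrogates`` state-space
    surrogates (simulated from the fitted parameters on the empirical
    beep schedule, then averaged) and of VAR surrogates are compared with
    empirical features.  Values of a feature are pooled across
    individuals and items, and one Pearson correlation per feature and
    route is returned (rows: feature; columns: ``kalman``, ``var``).
    A single-individual population yields NaN correlations.
    """
    if len(population) != len(fits):
        raise ValueError("one fit per series required")
    rng = np.random.default_rng(seed)
    emp: dict[str, list] = {f: [] for f in _FEATURES}
    kf: dict[str, list] = {f: [] for f in _FEATURES}
    var: dict[str, list] = {f: [] for f in _FEATURES}
    for series, fit in zip(population, fits):
        params = fit.params if isinstance(fit, FitResult) else fit
        e = _feature_vectors(compute_features(series, max_lag))
        kf_reps, var_reps = [], []
        try:
            vfit = var_fit(series)
        except ValueError:
            vfit = None
        for _ in range(n_surrogates):
            kf_reps.append(
                _feature_vectors(compute_features(_kalman_surrogate(params, series, rng), max_lag))
            )
            if vfit is not None:
                var_reps.append(
                    _feature_vectors(compute_features(var_simulate(vfit, series, rng), max_lag))
                )
        for f in _FEATURES:
            emp[f].append(e[f])
            kf[f].append(np.nanmean([r[f] for r in kf_reps], axis=0))
            if var_reps:
                var[f].append(np.nanmean([r[f] for r in var_reps], axis=0))
            else:
                var[f].append(np.full_like(e[f], np.nan))
    rows = {}
    for f in _FEATURES:
        e = np.concatenate(emp[f])
        rows[f] = {
            "kalman": _nan_corr(e, np.concatenate(kf[f])),
            "var": _nan_corr(e, np.concatenate(var[f])),
        }
    return pd.DataFrame(rows).T


def _nan_corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
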