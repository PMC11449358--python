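"""Core domain types and the generative model on the minute grid.

Mood in experience-sampling (EMA/ESM) studies is modelled as a
linear-Gaussian latent process evolving in one-minute steps,

    z_t = A z_{t-1} + h + C u_t + eps_t,   eps_t ~ N(0, Sigma)

observed noisily (identity observation map) only at beep times,

    x_t = z_t + eta_t,                     eta_t ~ N(0, Gamma).

``A`` is the per-minute dynamics matrix (diagonal: persistence of each
mood item; off-diagonal: cross-mood influence, entry a_ij = influence of
item j at t on item i at t+1), ``h`` a constant drive setting the resting
mood, ``C`` maps sparse one-hot context inputs (activity/company/location)
onto the mood items, and Sigma/Gamma are diagonal process/observation
noise covariances.  Because the grid step is one minute while beeps are
~90 minutes apart, a stable fitted ``A`` has eigenvalues close to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MoodSeries",
    "ModelParameters",
    "LatentGrid",
    "LatentTrajectory",
    "build_grid",
    "matrix_power_rescale",
    "simulate_forward",
    "hourly_dynamics",
]

_DIAG_TOL = 1e-9


@dataclass
class MoodSeries:
    """One individual's observed beeps.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    beep_times : (tau,) int array
        Strictly increasing minutes since the series start.
    ratings : (tau, N) float array
        Mood scores on their native numeric scale; ``NaN`` marks a
        missing item at a beep.
    inputs : (tau, K) array or None
        One-hot context indicators per beep (0/1), or None when the
        protocol recorded no context.
    item_names, input_names : list of str
        Column labels.
    valence_signs : (N,) array of +1/-1
        +1 for positively valenced items (e.g. cheerful), -1 for
        negatively valenced (e.g. sad).  Defaults to all +1; group-level
        eigenvector alignment needs the real convention.
    """

    subject_id: str
    beep_times: np.ndarray
    ratings: np.ndarray
    inputs: np.ndarray | None = None
    item_names: list[str] = field(default_factory=list)
    input_names: list[str] = field(default_factory=list)
    valence_signs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beep_times = np.asarray(self.beep_times, dtype=np.int64)
        self.ratings = np.atleast_2d(np.asarray(self.ratings, dtype=float))
        tau, n = self.ratings.shape
        if self.beep_times.ndim != 1 or self.beep_times.size != tau:
            raise ValueError(
                f"subject {self.subject_id!r}: ratings have {tau} rows but "
                f"{self.beep_times.size} beep times"
            )
        if tau > 1 and np.any(np.diff(self.beep_times) <= 0):
            bad = self.beep_times[1:][np.diff(self.beep_times) <= 0][0]
            raise ValueError(
                f"subject {self.subject_id!r}: beep times not strictly "
                f"increasing at minute {bad}"
            )
        if n < 2:
            raise ValueError("at least two mood items are required")
        if self.inputs is not None:
            self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
            if self.inputs.shape[0] != tau:
                raise ValueError("inputs row count must equal beep count")
            vals = self.inputs[np.isfinite(self.inputs)]
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("inputs must be binary 0/1")
        if not self.item_names:
            self.item_names = [f"item{i}" for i in range(n)]
        if self.inputs is not None and not self.input_names:
            self.input_names = [f"input{k}" for k in range(self.inputs.shape[1])]
        if self.valence_signs is None:
            self.valence_signs = np.ones(n)
        else:
            self.valence_signs = np.asarray(self.valence_signs, dtype=float)
            if not np.all(np.isin(self.valence_signs, (-1.0, 1.0))):
                raise ValueError("valence_signs entries must be +1 or -1")

    @property
    def n_beeps(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_items(self) -> int:
        return self.ratings.shape[1]

    @property
    def n_inputs(self) -> int:
        return 0 if self.inputs is None else self.inputs.shape[1]


@dataclass
class ModelParameters:
    """Parameters {A, h, C, Sigma, Gamma, mu0, P0} at the per-minute timescale.

    The observation map is fixed to the identity and never stored.  Sigma
    and Gamma are diagonal (uncorrelated noise across items); ``mu0``/``P0``
    give the Gaussian prior over the first latent state.
    """

    A: np.ndarray
    h: np.ndarray
    C: np.ndarray
    Sigma: np.ndarray
    Gamma: np.ndarray
    mu0: np.ndarray
    P0: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        self.h = np.asarray(self.h, dtype=float).reshape(n)
        self.C = np.asarray(self.C, dtype=float)
        if self.C.size == 0:
            self.C = self.C.reshape(n, 0)
        if self.C.shape[0] != n:
            raise ValueError("C must have N rows")
        for name in ("Sigma", "Gamma", "P0"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim == 1:
                m = np.diag(m)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            setattr(self, name, m)
        for name in ("Sigma", "Gamma"):
            m = getattr(self, name)
            if np.max(np.abs(m - np.diag(np.diag(m)))) > _DIAG_TOL:
                raise ValueError(f"{name} must be diagonal")
            if np.any(np.diag(m) < 0):
                raise ValueError(f"{name} diagonal must be non-negative")
        if not np.allclose(self.P0, self.P0.T, atol=1e-8):
            raise ValueError("P0 must be symmetric")
        if np.any(np.linalg.eigvalsh((self.P0 + self.P0.T) / 2) < -1e-10):
            raise ValueError("P0 must be positive semidefinite")
        self.mu0 = np.asarray(self.mu0, dtype=float).reshape(n)

    @property
    def n_items(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))

    def to_dict(self) -> dict:
        """JSON-serializable representation (row-major lists, shape tags)."""
        return {
            "timescale": "per-minute",
            "n_items": self.n_items,
            "n_inputs": self.n_inputs,
            "A": self.A.tolist(),
            "h": self.h.tolist(),
            "C": self.C.tolist(),
            "Sigma_diag": np.diag(self.Sigma).tolist(),
            "Gamma_diag": np.diag(self.Gamma).tolist(),
            "mu0": self.mu0.tolist(),
            "P0": self.P0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        n = d["n_items"]
        c = np.asarray(d["C"], dtype=float).reshape(n, d.get("n_inputs", 0))
        return cls(
            A=np.asarray(d["A"]),
            h=np.asarray(d["h"]),
            C=c,
            Sigma=np.diag(np.asarray(d["Sigma_diag"], dtype=float)),
            Gamma=np.diag(np.asarray(d["Gamma_diag"], dtype=float)),
            mu0=np.asarray(d["mu0"]),
            P0=np.asarray(d["P0"]),
        )


@dataclass
class LatentGrid:
    """One-minute grid from the first to the last beep of a series.

    ``obs_index[j]`` is the grid row of beep ``j``; ``input_at_grid`` is
    zero everywhere except at beep rows (context inputs are treated as
    active only at the minute they were reported).
    """

    grid_times: np.ndarray
    obs_index: np.ndarray
    input_at_grid: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.grid_times.size


@dataclass
class LatentTrajectory:
    """Latent state values on the grid; covariances when posterior."""

    times: np.ndarray
    means: np.ndarray
    covariances: np.ndarray | None = None


def build_grid(series: MoodSeries) -> LatentGrid:
    """Lay a 1-minute grid under a series and place its beeps and inputs.

    Returns a grid spanning the first to last beep inclusive.  Raises if
    two beeps collide on the same minute (the per-minute model cannot
    represent two observations of the same state).
    """
    t = series.beep_times
    if np.unique(t).size != t.size:
        dup = t[np.where(np.diff(np.sort(t)) == 0)[0][0]]
        raise ValueError(
            f"subject {series.subject_id!r}: duplicate beep at minute {dup}"
        )
    grid_times = np.arange(t[0], t[-1] + 1, dtype=np.int64)
    obs_index = (t - t[0]).astype(np.int64)
    k = series.n_inputs
    input_at_grid = np.zeros((grid_times.size, k))
    if k:
        input_at_grid[obs_index] = np.nan_to_num(series.inputs, nan=0.0)
    return LatentGrid(grid_times, obs_index, input_at_grid)


def matrix_power_rescale(A: np.ndarray, exponent: float) -> np.ndarray:
    """Real matrix power ``A**exponent`` via eigendecomposition.

    Computes ``V diag(lambda**exponent) V^-1`` with principal powers.
    Used to move the per-minute dynamics matrix between timescales (e.g.
    exponent 60 for hourly dynamics, 1/gap for re-expressing a per-gap
    transition per minute).

    Raises ``np.linalg.LinAlgError`` for (numerically) defective ``A``;
    warns when a non-integer power of an eigenvalue with non-positive
    real part forces a complex principal branch.
    """
    A = np.asarray(A, dtype=float)
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    w, v = np.linalg.eig(A)
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"matrix is defective or near-defective (eigenvector cond {cond:.2e})"
        )
    if float(exponent) != round(exponent) and np.any(w.real <= 0):
        warnings.warn(
            "non-integer power of eigenvalue(s) with non-positive real part; "
            "taking the principal complex branch",
            RuntimeWarning,
            stacklevel=2,
        )
    d = w.astype(complex) ** exponent
    out = v @ np.diag(d) @ np.linalg.inv(v)
    imag = np.max(np.abs(out.imag)) if out.size else 0.0
    scale = max(1.0, np.max(np.abs(out.real)))
    if imag > 1e-6 * scale:
        warnings.warn(
            f"matrix power has residual imaginary magnitude {imag:.2e}; "
            "returning the real part",
            RuntimeWarning,
            stacklevel=2,
        )
    return out.real


def hourly_dynamics(params: ModelParameters | np.ndarray) -> np.ndarray:
    """Dynamics over one hour: the per-minute matrix raised to the 60th power."""
    A = params.A if isinstance(params, ModelParameters) else np.asarray(params)
    return matrix_power_rescale(A, 60)


def simulate_forward(
    params: ModelParameters,
    grid: LatentGrid,
    seed: int | np.random.Generator,
    subject_id: str = "sim",
    item_names: list[str] | None = None,
    input_names: list[str] | None = None,
    valence_signs: np.ndarray | None = None,
) -> tuple[LatentTrajectory, MoodSeries]:
    """Roll the generative model minute-by-minute along a grid.

    The initial state is drawn from ``N(mu0 + C u_0, P0)``; each later
    minute applies ``z <- A z + h + C u_t + eps``.  Observations are
    emitted only at beep rows with noise ``N(0, Gamma)``.  Identical seed
    gives identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, k = params.n_items, params.n_inputs
    t_grid = grid.n_steps
    if grid.input_at_grid.shape[1] != k:
        raise ValueError(
            f"grid has {grid.input_at_grid.shape[1]} input columns, parameters expect {k}"
        )
    u = grid.input_at_grid
    sqrt_sig = np.sqrt(np.diag(params.Sigma))
    eps = rng.standard_normal((t_grid, n)) * sqrt_sig

    z = np.empty((t_grid, n))
    z0_noise = _sqrtm_psd(params.P0) @ rng.standard_normal(n)
    z[0] = params.mu0 + (params.C @ u[0] if k else 0.0) + z0_noise
    A, h, C = params.A, params.h, params.C
    for t in range(1, t_grid):
        drive = C @ u[t] if k else 0.0
        z[t] = A @ z[t - 1] + h + drive + eps[t]

    idx = grid.obs_index
    eta = rng.standard_normal((idx.size, n)) * np.sqrt(np.diag(params.Gamma))
    x = z[idx] + eta
    # MoodSeries carries observed one-hot context; continuous control
    # inputs (optimal-control replays) stay on the grid only
    u_obs = u[idx] if k else None
    if u_obs is not None and not np.all(np.isin(u_obs, (0.0, 1.0))):
        u_obs = None
    series = MoodSeries(
        subject_id=subject_id,
        beep_times=grid.grid_times[idx],
        ratings=x,
        inputs=u_obs,
        item_names=item_names or [f"item{i}" for i in range(n)],
        input_names=input_names or [f"input{j}" for j in range(k)],
        valence_signs=valence_signs,
    )
    return LatentTrajectory(times=grid.grid_times, means=z), series


def _sqrtm_psd(m: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix (eigen-based, clips tiny negatives)."""
    w, v = np.linalg.eigh((m + m.T) / 2)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
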