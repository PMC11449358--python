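"""Stability analytics of a fitted mood system.

The fitted dynamics matrix ``A`` is summarized through its
eigen-structure: eigenmodes (projections of the latent state onto the
eigenvectors) evolve independently with decay rate equal to their
eigenvalue, the dominant (largest-real-part) eigenvector is the
slowest-decaying mood combination, the determinant |A| measures overall
stability, and the noise-free system relaxes to the fixed point
``(I - A)^-1 h`` — shifted by a constant input ``u`` to
``(I - A)^-1 (h + C u)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import LatentTrajectory, ModelParameters, hourly_dynamics

__all__ = [
    "StabilitySummary",
    "stability_summary",
    "input_shifted_fixed_point",
    "project_eigenmodes",
    "sort_eigenpairs",
]

_COND_WARN = 1e8


def sort_eigenpairs(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition with a deterministic order and sign convention.

    Pairs are sorted by descending real part (ties: descending imaginary
    part); each unit-norm eigenvector is scaled so its largest-magnitude
    component has a positive real part.
    """
    w, v = np.linalg.eig(np.asarray(a, dtype=float))
    order = np.lexsort((-w.imag, -w.real))
    w, v = w[order], v[:, order]
    v = v / np.linalg.norm(v, axis=0, keepdims=True)
    for j in range(v.shape[1]):
        lead = np.argmax(np.abs(v[:, j]))
        if v[lead, j].real < 0:
            v[:, j] = -v[:, j]
    return w, v


@dataclass
class StabilitySummary:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    dominant_value: float
    dominant_vector: np.ndarray
    determinant: float
    fixed_point: np.ndarray | None
    timescale_tag: str
    fixed_point_reason: str | None = None


def stability_summary(
    a: np.ndarray,
    h: np.ndarray | None = None,
    timescale: str = "per-minute",
) -> StabilitySummary:
    """Eigen-structure, determinant and fixed point of a dynamics matrix.

    ``timescale='hourly'`` first converts ``a`` (and rescales ``h``
    accordingly via the geometric drive sum) to the one-hour step.  Real
    parts are the primary stability read-out; complex pairs are reported
    in full.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    h = np.zeros(n) if h is None else np.asarray(h, dtype=float).reshape(n)
    if timescale == "hourly":
        # fixed point is timescale-invariant: rescale h so (I-A60)^-1 h60 matches
        a60 = hourly_dynamics(a)
        h = (np.eye(n) - a60) @ np.linalg.solve(np.eye(n) - a, h) if _invertible(np.eye(n) - a) else h
        a = a60
    elif timescale != "per-minute":
        raise ValueError("timescale must be 'per-minute' or 'hourly'")
    w, v = sort_eigenpairs(a)
    det = float(np.linalg.det(a))
    fp, reason = None, None
    if _invertible(np.eye(n) - a):
        fp = np.linalg.solve(np.eye(n) - a, h)
    else:
        reason = "I - A is singular (eigenvalue at 1): no unique fixed point"
    return StabilitySummary(
        eigenvalues=w,
        eigenvectors=v,
        dominant_value=float(w[0].real),
        dominant_vector=v[:, 0],
        determinant=det,
        fixed_point=fp,
        timescale_tag=timescale,
        fixed_point_reason=reason,
    )


def _invertible(m: np.ndarray) -> bool:
    return np.linalg.cond(m) < 1e12


def input_shifted_fixed_point(
    a: np.ndarray, h: np.ndarray, c: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Resting state under a constant input: ``(I - A)^-1 (h + C u)``."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    m = np.eye(n) - a
    if not _invertible(m):
        raise np.linalg.LinAlgError("I - A is singular: no fixed point")
    drive = np.asarray(h, dtype=float).reshape(n)
    c = np.asarray(c, dtype=float)
    if c.size:
        drive = drive + c @ np.asarray(u, dtype=float)
    return np.linalg.solve(m, drive)


def project_eigenmodes(
    trajectory: LatentTrajectory | np.ndarray, summary: StabilitySummary
) -> np.ndarray:
    """Mode trajectories ``V^-1 z_t``: coordinates that decay independently.

    Returns a (T, N) complex array (real for real spectra).  Attaches a
    warning when the eigenvector matrix is ill-conditioned, in which case
    mode amplitudes are numerically unreliable.
    """
    z = trajectory.means if isinstance(trajectory, LatentTrajectory) else np.asarray(trajectory)
    v = summary.eigenvectors
    cond = np.linalg.cond(v)
    if cond > _COND_WARN:
        warnings.warn(
            f"eigenvector matrix condition number {cond:.2e}: eigenmode "
            "projection is numerically unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    modes = np.linalg.solve(v, np.atleast_2d(z).T).T
    return modes
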