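"""Controllability analysis and optimal-control input planning.

The controllability matrix ``[C, AC, A^2 C, ..., A^{n-1} C]`` describes
which mood directions external context inputs can move and at what
energy cost: its left singular vectors define an energy ellipsoid in
which directions with larger singular values are displaced further per
unit input energy.  Input planning solves the finite-horizon
linear-quadratic tracking problem — steer the latent mood state to a
target (e.g. high positive, low negative items) while penalizing input
effort — or, for exact terminal targeting, the minimum-energy
(pseudoinverse) control problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .model import LatentTrajectory, ModelParameters

__all__ = [
    "ControllabilitySummary",
    "ControlPlan",
    "controllability_summary",
    "controllability_gramian",
    "reachability_gain",
    "min_energy_input",
    "plan_optimal_inputs",
]


@dataclass
class ControllabilitySummary:
    ctrb_matrix: np.ndarray
    singular_values: np.ndarray
    left_singular_vectors: np.ndarray
    horizon_n: int
    rank: int


@dataclass
class ControlPlan:
    target_state: np.ndarray
    horizon: int
    input_sequence: np.ndarray
    predicted_trajectory: LatentTrajectory
    input_cost_weight: np.ndarray
    state_cost_weight: np.ndarray
    terminal_error: float


def controllability_summary(
    a: np.ndarray, c: np.ndarray, horizon_n: int | None = None
) -> ControllabilitySummary:
    """Controllability matrix ``[C, AC, ..., A^{m-1}C]`` and its SVD.

    ``horizon_n`` defaults to the state dimension N (the Kalman rank
    horizon).  Left singular vectors are unit norm, singular values
    descending.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    n = a.shape[0]
    if c.ndim != 2 or c.shape[0] != n or c.shape[1] == 0:
        raise ValueError("system has no inputs (C must be N x K with K >= 1)")
    m = horizon_n or n
    blocks = [c]
    for _ in range(m - 1):
        blocks.append(a @ blocks[-1])
    ctrb = np.concatenate(blocks, axis=1)
    u, s, _ = np.linalg.svd(ctrb, full_matrices=False)
    rank = int(np.linalg.matrix_rank(ctrb))
    return ControllabilitySummary(
        ctrb_matrix=ctrb,
        singular_values=s,
        left_singular_vectors=u,
        horizon_n=m,
        rank=rank,
    )


def controllability_gramian(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Infinite-horizon discrete controllability Gramian sum A^k C C' A'^k.

    Offered for users who expect the Gramian proper rather than the
    finite block controllability matrix; requires a stable ``a``.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.max(np.abs(np.linalg.eigvals(a))) >= 1.0:
        raise ValueError("Gramian requires spectral radius < 1")
    return solve_discrete_lyapunov(a, c @ c.T)


def reachability_gain(summary: ControllabilitySummary, direction_index: int) -> float:
    """Displacement per unit input energy along a left singular direction."""
    return float(summary.singular_values[direction_index])


def _free_response(a: np.ndarray, h: np.ndarray, z0: np.ndarray, horizon: int):
    """States z_1..z_H of the input-free noise-free rollout from z0."""
    n = a.shape[0]
    z = np.empty((horizon, n))
    cur = z0
    for t in range(horizon):
        cur = a @ cur + h
        z[t] = cur
    return z


def _reach_matrix(a: np.ndarray, c: np.ndarray, horizon: int) -> np.ndarray:
    """Map from stacked inputs (u_0..u_{H-1}) to terminal displacement."""
    blocks = [c]
    for _ in range(horizon - 1):
        blocks.insert(0, a @ blocks[0])
    return np.concatenate(blocks, axis=1)


def min_energy_input(
    params: ModelParameters,
    start: np.ndarray,
    target: np.ndarray,
    horizon: int,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Minimum-total-energy input sequence reaching ``target`` exactly at the horizon.

    Solves ``target = A^H z0 + sum_k A^k h + R u`` for the smallest-norm
    stacked ``u`` via the pseudoinverse of the horizon reachability
    matrix; raises when the required displacement is outside its column
    space (the target is unreachable with these inputs).
    Returns a (horizon, K) array of inputs ``u_0 .. u_{H-1}``, where
    ``u_t`` acts on the transition from ``z_t`` to ``z_{t+1}``.
    """
    a, c, h = params.A, params.C, params.h
    if c.shape[1] == 0:
        raise ValueError("system has no inputs")
    start = np.asarray(start, dtype=float).reshape(-1)
    target = np.asarray(target, dtype=float).reshape(-1)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    free = _free_response(a, h, start, horizon)[-1]
    d = target - free
    r = _reach_matrix(a, c, horizon)
    u_stack, *_ = np.linalg.lstsq(r, d, rcond=None)
    resid = float(np.linalg.norm(r @ u_stack - d))
    if resid > rtol * (1.0 + float(np.linalg.norm(d))):
        raise ValueError(
            f"target unreachable with these inputs: residual norm {resid:.3e}"
        )
    return u_stack.reshape(horizon, c.shape[1])


def _cost_matrix(weight, n: int) -> np.ndarray:
    w = np.asarray(weight, dtype=float)
    if w.ndim == 0:
        return float(w) * np.eye(n)
    if w.ndim == 1:
        return np.diag(w)
    return w


def plan_optimal_inputs(
    params: ModelParameters,
    target: np.ndarray,
    horizon: int,
    state_cost=1.0,
    input_cost=1.0,
    start: np.ndarray | None = None,
    box_constraints: tuple[float, float] | None = None,
    require_reachable: bool = False,
) -> ControlPlan:
    """Finite-horizon linear-quadratic tracking plan towards a target mood state.

    Minimizes ``sum_t (z_t - g)' Q (z_t - g) + sum_t u_t' R u_t`` subject
    to ``z_{t+1} = A z_t + h + C u_t``, solved exactly by a backward
    Riccati-style recursion.  Inputs are continuous-valued; an optional
    box constraint (e.g. ``(0, 1)`` for one-hot-like inputs) is handled
    by projected gradient iterations and flagged approximate.
    """
    a, c, h = params.A, params.C, params.h
    n, k = params.n_items, params.n_inputs
    if k == 0:
        raise ValueError("system has no inputs")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    g = np.asarray(target, dtype=float).reshape(n)
    z0 = params.mu0 if start is None else np.asarray(start, dtype=float).reshape(n)
    q = _cost_matrix(state_cost, n)
    r = _cost_matrix(input_cost, k)
    if np.any(np.linalg.eigvalsh(r) <= 0):
        raise ValueError("input cost must be positive definite")

    if require_reachable:
        reach = _reach_matrix(a, c, horizon)
        d = g - _free_response(a, h, z0, horizon)[-1]
        proj, *_ = np.linalg.lstsq(reach, d, rcond=None)
        resid = d - reach @ proj
        if np.linalg.norm(resid) > 1e-8 * (1.0 + np.linalg.norm(d)):
            idx = int(np.argmax(np.abs(resid)))
            raise ValueError(
                f"target component {idx} unreachable (residual {resid[idx]:.3e})"
            )

    if box_constraints is None:
        u_seq = _lq_tracking(a, c, h, q, r, g, z0, horizon)
    else:
        u_seq = _box_constrained_qp(a, c, h, q, r, g, z0, horizon, box_constraints)

    z = np.empty((horizon + 1, n))
    z[0] = z0
    for t in range(horizon):
        z[t + 1] = a @ z[t] + h + c @ u_seq[t]
    traj = LatentTrajectory(times=np.arange(horizon + 1), means=z)
    return ControlPlan(
        target_state=g,
        horizon=horizon,
        input_sequence=u_seq,
        predicted_trajectory=traj,
        input_cost_weight=r,
        state_cost_weight=q,
        terminal_error=float(np.linalg.norm(z[-1] - g)),
    )


def _lq_tracking(a, c, h, q, r, g, z0, horizon):
    """Backward value recursion for the affine LQ tracking problem."""
    n, k = a.shape[0], c.shape[1]
    w = np.zeros((n, n))  # V_H(z) = 0 (terminal state cost folded into stages)
    wv = np.zeros(n)
    gains = []
    for _ in range(horizon):
        m = q + w
        mvec = q @ g + wv
        s = r + c.T @ m @ c
        s_inv = np.linalg.inv(s)
        big_l = -s_inv @ (c.T @ m @ a)
        lit_l = s_inv @ (c.T @ (mvec - m @ h))
        f = a + c @ big_l
        fv = h + c @ lit_l
        w_new = big_l.T @ r @ big_l + f.T @ m @ f
        wv_new = f.T @ mvec - big_l.T @ r @ lit_l - f.T @ m @ fv
        w = 0.5 * (w_new + w_new.T)
        wv = wv_new
        gains.append((big_l, lit_l))
    gains.reverse()
    u_seq = np.empty((horizon, k))
    z = z0
    for t, (big_l, lit_l) in enumerate(gains):
        u = big_l @ z + lit_l
        u_seq[t] = u
        z = a @ z + h + c @ u
    return u_seq


def _box_constrained_qp(a, c, h, q, r, g, z0, horizon, box, n_iter=2000):
    """Projected-gradient solve of the stacked tracking QP (approximate)."""
    n, k = a.shape[0], c.shape[1]
    # z_stack = M u_stack + b ; stage costs assembled densely
    b = _free_response(a, h, z0, horizon).reshape(-1)
    m_mat = np.zeros((horizon * n, horizon * k))
    apow = [np.eye(n)]
    for _ in range(horizon - 1):
        apow.append(a @ apow[-1])
    for t in range(horizon):
        for s in range(t + 1):
            m_mat[t * n : (t + 1) * n, s * k : (s + 1) * k] = apow[t - s] @ c
    qbar = np.kron(np.eye(horizon), q)
    rbar = np.kron(np.eye(horizon), r)
    hess = m_mat.T @ qbar @ m_mat + rbar
    lin = m_mat.T @ qbar @ (np.tile(g, horizon) - b)
    lo, hi = box
    u = np.clip(np.linalg.solve(hess, lin), lo, hi)
    step = 1.0 / np.linalg.eigvalsh(hess)[-1]
    for _ in range(n_iter):
        grad = hess @ u - lin
        u_new = np.clip(u - step * grad, lo, hi)
        if np.max(np.abs(u_new - u)) < 1e-12:
            u = u_new
            break
        u = u_new
    return u.reshape(horizon, k)
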