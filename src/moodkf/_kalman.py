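"""Compiled Kalman filter / RTS smoother kernels for the minute grid.

The E-step walks every minute of the grid (tens of thousands of steps for
a two-week series), so the recursions are JIT-compiled with numba.  The
observation map is the identity and Gamma is diagonal, which lets the
update at a beep be done as a sequence of scalar-observation updates —
one per non-missing item — in Joseph form.  The sum of the scalar
predictive log-densities equals the joint Gaussian predictive
log-density of the observed sub-vector, so the marginal log-likelihood
accumulates exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def filter_pass(A, h, C, Sigma, gamma_diag, mu0, P0, u_grid, y, obs_mask):
    """Forward pass. Returns (pred_m, pred_P, filt_m, filt_P, loglik).

    y : (T, N) observations, ignored where obs_mask is False.
    u_grid : (T, K) inputs on the grid (K may be 0).
    """
    T, N = y.shape
    K = C.shape[1]
    pred_m = np.empty((T, N))
    pred_P = np.empty((T, N, N))
    filt_m = np.empty((T, N))
    filt_P = np.empty((T, N, N))
    eye = np.eye(N)
    loglik = 0.0
    log2pi = np.log(2.0 * np.pi)

    m = mu0.copy()
    if K > 0:
        m = m + C @ u_grid[0]
    P = P0.copy()

    for t in range(T):
        if t > 0:
            m = A @ m + h
            if K > 0:
                m = m + C @ u_grid[t]
            P = A @ P @ A.T + Sigma
            P = 0.5 * (P + P.T)
        pred_m[t] = m
        pred_P[t] = P
        for i in range(N):
            if obs_mask[t, i]:
                s = P[i, i] + gamma_diag[i]
                if s <= 0.0:
                    raise np.linalg.LinAlgError
                innov = y[t, i] - m[i]
                loglik += -0.5 * (log2pi + np.log(s) + innov * innov / s)
                kgain = P[:, i] / s
                m = m + kgain * innov
                # Joseph form: (I - K e_i^T) P (I - K e_i^T)^T + g_i K K^T
                ik = eye.copy()
                for r in range(N):
                    ik[r, i] -= kgain[r]
                P = ik @ P @ ik.T + gamma_diag[i] * np.outer(kgain, kgain)
                P = 0.5 * (P + P.T)
        filt_m[t] = m
        filt_P[t] = P
    return pred_m, pred_P, filt_m, filt_P, loglik


@njit(cache=True)
def smooth_pass(A, pred_m, pred_P, filt_m, filt_P):
    """Rauch–Tung–Striebel backward pass.

    Returns (sm_m, sm_P, lag1) where lag1[t] = Cov(z_{t+1}, z_t | all obs).
    """
    T, N = filt_m.shape
    sm_m = np.empty((T, N))
    sm_P = np.empty((T, N, N))
    lag1 = np.empty((T - 1, N, N)) if T > 1 else np.empty((0, N, N))
    sm_m[T - 1] = filt_m[T - 1]
    sm_P[T - 1] = filt_P[T - 1]
    for t in range(T - 2, -1, -1):
        # J = filt_P[t] A^T pred_P[t+1]^{-1}
        j = np.linalg.solve(pred_P[t + 1], A @ filt_P[t]).T
        sm_m[t] = filt_m[t] + j @ (sm_m[t + 1] - pred_m[t + 1])
        dp = sm_P[t + 1] - pred_P[t + 1]
        p = filt_P[t] + j @ dp @ j.T
        sm_P[t] = 0.5 * (p + p.T)
        lag1[t] = sm_P[t + 1] @ j.T
    return sm_m, sm_P, lag1


@njit(cache=True)
def simulate_pass(A, h, C, u_grid, z0, eps):
    """Roll z_{t} = A z_{t-1} + h + C u_t + eps_t from a given z0."""
    T, N = eps.shape
    K = C.shape[1]
    z = np.empty((T, N))
    z[0] = z0
    for t in range(1, T):
        zt = A @ z[t - 1] + h + eps[t]
        if K > 0:
            zt = zt + C @ u_grid[t]
        z[t] = zt
    return z


@njit(cache=True)
def transition_suffstats(sm_m, sm_P, lag1, u_grid):
    """Sufficient statistics over the T-1 minute transitions for the M-step.

    With predictor p_t = [z_{t-1}; 1; u_t] and response z_t, returns the
    expected cross-moment blocks
      S11 = sum E[z_t z_t^T],  S10 = sum E[z_t z_{t-1}^T],
      S00 = sum E[z_{t-1} z_{t-1}^T],
      s1 = sum E[z_t],  s0 = sum E[z_{t-1}],
      Z1U = sum E[z_t] u_t^T,  Z0U = sum E[z_{t-1}] u_t^T,
      Suu = sum u_t u_t^T,  su = sum u_t.
    """
    T, N = sm_m.shape
    K = u_grid.shape[1]
    S11 = np.zeros((N, N))
    S10 = np.zeros((N, N))
    S00 = np.zeros((N, N))
    s1 = np.zeros(N)
    s0 = np.zeros(N)
    Z1U = np.zeros((N, K))
    Z0U = np.zeros((N, K))
    Suu = np.zeros((K, K))
    su = np.zeros(K)
    for t in range(1, T):
        m1 = sm_m[t]
        m0 = sm_m[t - 1]
        S11 += sm_P[t] + np.outer(m1, m1)
        S10 += lag1[t - 1] + np.outer(m1, m0)
        S00 += sm_P[t - 1] + np.outer(m0, m0)
        s1 += m1
        s0 += m0
        if K > 0:
            ut = u_grid[t]
            Z1U += np.outer(m1, ut)
            Z0U += np.outer(m0, ut)
            Suu += np.outer(ut, ut)
            su += ut
    return S11, S10, S00, s1, s0, Z1U, Z0U, Suu, su
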