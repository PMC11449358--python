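"""Controllability structure and optimal input planning."""

import numpy as np
import pytest

from moodkf.control import (
    controllability_gramian,
    controllability_summary,
    min_energy_input,
    plan_optimal_inputs,
    reachability_gain,
)
from moodkf.model import ModelParameters, MoodSeries, build_grid, simulate_forward


def make_params(a, c, h=None, mu0=None):
    n = a.shape[0]
    return ModelParameters(
        A=a,
        h=np.zeros(n) if h is None else h,
        C=c,
        Sigma=np.zeros((n, n)),
        Gamma=np.zeros((n, n)),
        mu0=np.zeros(n) if mu0 is None else mu0,
        P0=np.zeros((n, n)),
    )


def replay_plan(params, start, u_seq):
    """Noise-free forward simulation of a planned input sequence."""
    from moodkf.model import LatentGrid

    horizon = u_seq.shape[0]
    times = np.arange(horizon + 1, dtype=np.int64)
    input_at_grid = np.zeros((horizon + 1, params.n_inputs))
    input_at_grid[1:] = u_seq
    grid = LatentGrid(
        grid_times=times,
        obs_index=np.array([0, horizon], dtype=np.int64),
        input_at_grid=input_at_grid,
    )
    p = ModelParameters(
        A=params.A, h=params.h, C=params.C,
        Sigma=np.zeros_like(params.A), Gamma=np.zeros_like(params.A),
        mu0=start, P0=np.zeros_like(params.A),
    )
    traj, _ = simulate_forward(p, grid, seed=0)
    return traj.means[horizon]


class TestControllabilitySummary:
    def test_identity_dynamics_single_input_rank_one(self):
        c = np.array([[1.0], [2.0]])
        s = controllability_summary(np.eye(2), c)
        np.testing.assert_allclose(s.ctrb_matrix, np.hstack([c, c]))
        assert s.rank == 1

    def test_shift_system_is_fully_controllable(self):
        a = np.array([[0.0, 1.0], [0.0, 0.0]])
        c = np.array([[0.0], [1.0]])
        s = controllability_summary(a, c)
        np.testing.assert_allclose(s.ctrb_matrix, [[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(s.singular_values, [1.0, 1.0])
        assert s.rank == 2

    def test_rank_matches_brute_force_construction(self, rng):
        a = rng.standard_normal((4, 4)) * 0.4
        c = rng.standard_normal((4, 2))
        s = controllability_summary(a, c)
        blocks = [np.linalg.matrix_power(a, k) @ c for k in range(4)]
        assert s.rank == np.linalg.matrix_rank(np.hstack(blocks))

    def test_no_inputs_is_error(self):
        with pytest.raises(ValueError, match="no inputs"):
            controllability_summary(np.eye(2), np.zeros((2, 0)))

    def test_gramian_solves_lyapunov_sum(self, rng):
        a = rng.standard_normal((3, 3))
        a *= 0.6 / np.max(np.abs(np.linalg.eigvals(a)))
        c = rng.standard_normal((3, 2))
        w = controllability_gramian(a, c)
        brute = sum(
            np.linalg.matrix_power(a, k) @ c @ c.T @ np.linalg.matrix_power(a, k).T
            for k in range(500)
        )
        np.testing.assert_allclose(w, brute, atol=1e-8)


class TestReachabilityGain:
    def test_orthonormal_ctrb_has_unit_gains(self):
        s = controllability_summary(np.zeros((2, 2)), np.eye(2))
        assert reachability_gain(s, 0) == pytest.approx(1.0)
        assert reachability_gain(s, 1) == pytest.approx(1.0)

    def test_gains_are_ordered(self, rng):
        a = rng.standard_normal((3, 3)) * 0.5
        c = rng.standard_normal((3, 2))
        s = controllability_summary(a, c)
        assert reachability_gain(s, 0) >= reachability_gain(s, 2)

    def test_top_direction_moves_further_per_unit_energy(self, rng):
        a = rng.standard_normal((3, 3)) * 0.5
        c = rng.standard_normal((3, 1))
        params = make_params(a, c)
        s = controllability_summary(a, c)
        _, _, vt = np.linalg.svd(s.ctrb_matrix, full_matrices=False)
        # unit-energy inputs along extreme right-singular directions,
        # applied most-delayed-block-first so block k multiplies A^k C
        def displacement(v_right):
            u_seq = v_right.reshape(3, 1)[::-1]
            return np.linalg.norm(replay_plan(params, np.zeros(3), u_seq))

        assert displacement(vt[0]) > displacement(vt[-1])


class TestMinEnergyInput:
    def test_free_response_needs_zero_input(self, rng):
        a = rng.standard_normal((2, 2)) * 0.4
        c = rng.standard_normal((2, 1))
        h = rng.standard_normal(2)
        params = make_params(a, c, h=h)
        start = rng.standard_normal(2)
        free = start.copy()
        for _ in range(5):
            free = a @ free + h
        u = min_energy_input(params, start, free, horizon=5)
        np.testing.assert_allclose(u, 0.0, atol=1e-8)

    def test_memoryless_scalar_single_step(self):
        params = make_params(
            np.zeros((2, 2)), np.eye(2), h=np.array([0.3, -0.2])
        )
        target = np.array([1.0, 2.0])
        u = min_energy_input(params, np.zeros(2), target, horizon=1)
        np.testing.assert_allclose(u[0], target - params.h, atol=1e-10)

    def test_replay_through_simulator_hits_target(self, rng):
        a = rng.standard_normal((3, 3)) * 0.5
        c = rng.standard_normal((3, 2))
        h = rng.standard_normal(3)
        params = make_params(a, c, h=h)
        start = rng.standard_normal(3)
        target = rng.standard_normal(3)
        u = min_energy_input(params, start, target, horizon=6)
        np.testing.assert_allclose(replay_plan(params, start, u), target, atol=1e-6)

    def test_energy_cheaper_along_top_singular_direction(self, rng):
        a = rng.standard_normal((3, 3)) * 0.5
        c = rng.standard_normal((3, 1))
        params = make_params(a, c)
        s = controllability_summary(a, c)
        top, bottom = s.left_singular_vectors[:, 0], s.left_singular_vectors[:, -1]
        e = lambda d: np.sum(min_energy_input(params, np.zeros(3), d, horizon=3) ** 2)
        assert e(top) < e(bottom)

    def test_unreachable_target_reports_residual(self):
        params = make_params(np.eye(2), np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError, match="residual"):
            min_energy_input(params, np.zeros(2), np.array([0.0, 1.0]), horizon=3)


def lq_oracle(params, target, horizon, q_scale, r_scale, start):
    """Independent dense normal-equations solve of the tracking problem."""
    a, c, h = params.A, params.C, params.h
    n, k = a.shape[0], c.shape[1]
    b = np.empty((horizon, n))
    cur = start
    for t in range(horizon):
        cur = a @ cur + h
        b[t] = cur
    m = np.zeros((horizon * n, horizon * k))
    apow = [np.eye(n)]
    for _ in range(horizon - 1):
        apow.append(a @ apow[-1])
    for t in range(horizon):
        for s in range(t + 1):
            m[t * n : (t + 1) * n, s * k : (s + 1) * k] = apow[t - s] @ c
    qbar = q_scale * np.eye(horizon * n)
    rbar = r_scale * np.eye(horizon * k)
    rhs = m.T @ qbar @ (np.tile(target, horizon) - b.reshape(-1))
    u = np.linalg.solve(m.T @ qbar @ m + rbar, rhs)
    return u.reshape(horizon, k)


class TestPlanOptimalInputs:
    def test_resting_at_fixed_point_needs_no_input(self, rng):
        a = rng.standard_normal((2, 2)) * 0.4
        c = rng.standard_normal((2, 1))
        h = rng.standard_normal(2)
        fp = np.linalg.solve(np.eye(2) - a, h)
        params = make_params(a, c, h=h, mu0=fp)
        plan = plan_optimal_inputs(params, fp, horizon=8)
        np.testing.assert_allclose(plan.input_sequence, 0.0, atol=1e-8)
        assert plan.terminal_error < 1e-8

    def test_memoryless_identity_actuation_one_step(self):
        params = make_params(np.zeros((2, 2)), np.eye(2))
        target = np.array([1.0, -1.0])
        plan = plan_optimal_inputs(params, target, horizon=1, input_cost=1e-12)
        np.testing.assert_allclose(plan.input_sequence[0], target, atol=1e-6)
        assert plan.terminal_error < 1e-6

    def test_matches_dense_normal_equations_oracle(self, rng):
        a = rng.standard_normal((4, 4))
        a *= 0.9 / np.max(np.abs(np.linalg.eigvals(a)))
        c = rng.standard_normal((4, 2))
        h = 0.1 * rng.standard_normal(4)
        params = make_params(a, c)
        params.h[:] = h
        start = rng.standard_normal(4)
        target = np.array([1.0, 1.0, -1.0, -1.0])
        plan = plan_optimal_inputs(
            params, target, horizon=12, state_cost=1.0, input_cost=0.5, start=start
        )
        expected = lq_oracle(params, target, 12, 1.0, 0.5, start)
        np.testing.assert_allclose(plan.input_sequence, expected, atol=1e-6)

    def test_terminal_error_shrinks_as_input_cost_vanishes(self, rng):
        a = rng.standard_normal((3, 3)) * 0.5
        c = rng.standard_normal((3, 3))
        params = make_params(a, c)
        target = np.ones(3)
        errs = [
            plan_optimal_inputs(params, target, horizon=6, input_cost=r).terminal_error
            for r in (1.0, 1e-2, 1e-4)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_box_constraint_respected(self, rng):
        a = rng.standard_normal((2, 2)) * 0.4
        c = rng.standard_normal((2, 1))
        params = make_params(a, c)
        plan = plan_optimal_inputs(
            params, 5 * np.ones(2), horizon=4, box_constraints=(0.0, 1.0)
        )
        assert np.all(plan.input_sequence >= -1e-12)
        assert np.all(plan.input_sequence <= 1.0 + 1e-12)

    def test_predicted_trajectory_consistent_with_terminal_error(self, rng):
        a = rng.standard_normal((2, 2)) * 0.4
        c = rng.standard_normal((2, 1))
        params = make_params(a, c)
        target = np.array([1.0, -1.0])
        plan = plan_optimal_inputs(params, target, horizon=5)
        final = replay_plan(params, params.mu0, plan.input_sequence)
        np.testing.assert_allclose(plan.predicted_trajectory.means[-1], final, atol=1e-9)
        assert plan.terminal_error == pytest.approx(
            float(np.linalg.norm(final - target)), abs=1e-9
        )

    def test_one_dimensional_persistence_monotonicity(self):
        # with c fixed, the 1-D controllability norm sqrt(sum a^{2k}) is
        # strictly increasing in |a|: persistence accumulates input effect
        c = np.array([[1.0]])
        sv = lambda a: controllability_summary(np.array([[a]]), c, horizon_n=4).singular_values[0]
        values = [sv(a) for a in (0.2, 0.5, 0.9, 0.99)]
        assert values == sorted(values)
        np.testing.assert_allclose(
            values, [np.sqrt(sum(a ** (2 * k) for k in range(4))) for a in (0.2, 0.5, 0.9, 0.99)]
        )
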