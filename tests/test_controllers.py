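"""PID arithmetic and protocol gains; MPC against an independent stacked
KKT quadratic-program oracle, optimality sanity checks, and closed-loop
behavior on exact linear dynamics."""

import numpy as np
import pytest

import manifoldmpc as mm
from manifoldmpc.controllers import MpcSpec, mpc_cost, mpc_solve


class TestPid:
    def test_zero_error_zero_history_gives_zero_input(self):
        v, _ = mm.pid_step(np.zeros(2), mm.PidState(), mm.default_pid_gains())
        np.testing.assert_allclose(v, 0.0)

    def test_proportional_only(self):
        gains = mm.PidGains(K_P=np.eye(2), K_I=np.zeros((2, 2)),
                            K_D=np.zeros((2, 2)))
        v, _ = mm.pid_step(np.array([1.0, 2.0]), mm.PidState(), gains)
        np.testing.assert_allclose(v, [1.0, 2.0])

    def test_default_gain_matrices(self):
        g = mm.default_pid_gains()
        np.testing.assert_allclose(g.K_P, [[20.0, 20.0], [5.0, 20.0]])
        np.testing.assert_allclose(g.K_I, [[0.9, 0.9], [0.1, 0.1]])
        np.testing.assert_allclose(g.K_D, [[0.01, 0.01], [0.01, 0.01]])

    def test_integral_and_derivative_accumulation(self):
        gains = mm.PidGains(K_P=np.zeros((2, 2)), K_I=np.eye(2), K_D=np.eye(2))
        state = mm.PidState()
        e1 = np.array([1.0, 0.0])
        v1, state = mm.pid_step(e1, state, gains)
        np.testing.assert_allclose(v1, [2.0, 0.0])   # integral 1 + derivative 1
        e2 = np.array([1.0, 1.0])
        v2, state = mm.pid_step(e2, state, gains)
        # integral (2, 1); derivative (0, 1)
        np.testing.assert_allclose(v2, [2.0, 2.0])

    def test_all_zero_gains_always_zero_input(self):
        gains = mm.PidGains(*[np.zeros((2, 2))] * 3)
        state = mm.PidState()
        rng = np.random.default_rng(0)
        for _ in range(50):
            v, state = mm.pid_step(rng.normal(size=2), state, gains)
            np.testing.assert_allclose(v, 0.0)

    def test_anti_windup_bound(self):
        gains = mm.PidGains(K_P=np.zeros((2, 2)), K_I=np.eye(2),
                            K_D=np.zeros((2, 2)), integral_bound=1.5)
        state = mm.PidState()
        for _ in range(10):
            v, state = mm.pid_step(np.ones(2), state, gains)
        np.testing.assert_allclose(v, 1.5)


def _kkt_qp_oracle(z0, ref, A, B, spec, v_prev):
    """Independent dense QP: decision variables are the stacked states
    z_1..z_T *and* inputs v_0..v_{T-1}; the dynamics are equality
    constraints solved through the KKT system."""
    T = spec.horizon
    k, m = B.shape
    nz, nv = T * k, T * m
    n = nz + nv
    P = np.zeros((n, n))
    q = np.zeros(n)
    for i in range(1, T + 1):
        Wi = spec.S if i == T else spec.Q
        sl = slice((i - 1) * k, i * k)
        P[sl, sl] += 2 * Wi
        q[sl] += -2 * Wi @ ref[i - 1]
    D = np.zeros((nv, nv))
    d = np.zeros(nv)
    for i in range(T):
        D[i * m:(i + 1) * m, i * m:(i + 1) * m] = np.eye(m)
        if i > 0:
            D[i * m:(i + 1) * m, (i - 1) * m:i * m] = -np.eye(m)
    d[:m] = -v_prev
    Rbar = np.kron(np.eye(T), spec.R)
    P[nz:, nz:] += 2 * D.T @ Rbar @ D
    q[nz:] += 2 * D.T @ Rbar @ d
    # equality constraints C x = b:  z_{i+1} - A z_i - B v_i = 0
    C = np.zeros((nz, n))
    b = np.zeros(nz)
    for i in range(T):
        rows = slice(i * k, (i + 1) * k)
        C[rows, i * k:(i + 1) * k] = np.eye(k)
        if i > 0:
            C[rows, (i - 1) * k:i * k] = -A
        else:
            b[rows] = A @ z0
        C[rows, nz + i * m:nz + (i + 1) * m] = -B
    KKT = np.block([[P, C.T], [C, np.zeros((nz, nz))]])
    rhs = np.concatenate([-q, b])
    sol = np.linalg.solve(KKT, rhs)
    return sol[nz:n].reshape(T, m)


class TestMpc:
    def test_default_spec_protocol_constants(self):
        spec = mm.default_mpc_spec()
        assert spec.horizon == 10
        np.testing.assert_allclose(spec.Q, np.eye(2))
        np.testing.assert_allclose(spec.S, np.eye(2))
        np.testing.assert_allclose(spec.R, 0.001 * np.eye(2))
        assert spec.v_bounds is None

    def test_already_at_equilibrium_zero_increment_zero_cost(self):
        """If A z* + B v_prev = z*, holding v_prev is optimal: dv = 0 and
        the cost vanishes."""
        A = np.array([[0.9, 0.0], [0.0, 0.8]])
        B = np.eye(2)
        z_star = np.array([1.0, 2.0])
        v_prev = z_star - A @ z_star
        ref = np.tile(z_star, (10, 1))
        seq, v0 = mm.mpc_solve(z_star, ref, A, B, v_prev=v_prev)
        np.testing.assert_allclose(seq, np.tile(v_prev, (10, 1)), atol=1e-9)
        cost = mpc_cost(z_star, ref, A, B, mm.default_mpc_spec(), v_prev, seq)
        assert cost == pytest.approx(0.0, abs=1e-16)

    def test_scalar_toy_matches_kkt_oracle(self):
        spec = MpcSpec(horizon=3, Q=np.eye(1), R=np.eye(1) * 0.001,
                       S=np.eye(1))
        A, B = np.array([[0.5]]), np.array([[1.0]])
        ref = np.tile([2.0], (3, 1))
        seq, _ = mm.mpc_solve(np.array([0.0]), ref, A, B, spec,
                              v_prev=np.zeros(1))
        oracle = _kkt_qp_oracle(np.array([0.0]), ref, A, B, spec, np.zeros(1))
        np.testing.assert_allclose(seq, oracle, atol=1e-6)

    def test_random_instances_match_kkt_oracle(self):
        """50 random unconstrained 2-D linear-quadratic instances agree
        with the stacked QP to 1e-6."""
        rng = np.random.default_rng(0)
        spec = mm.default_mpc_spec()
        for _ in range(50):
            A = rng.normal(scale=0.5, size=(2, 2))
            B = rng.normal(scale=0.5, size=(2, 2))
            z0 = rng.normal(size=2)
            ref = rng.normal(size=(10, 2))
            v_prev = rng.normal(size=2)
            seq, v0 = mm.mpc_solve(z0, ref, A, B, spec, v_prev=v_prev)
            oracle = _kkt_qp_oracle(z0, ref, A, B, spec, v_prev)
            np.testing.assert_allclose(seq, oracle, atol=1e-6)
            np.testing.assert_allclose(v0, oracle[0], atol=1e-6)

    def test_optimum_beats_zero_increment_sequence(self):
        rng = np.random.default_rng(1)
        spec = mm.default_mpc_spec()
        for _ in range(20):
            A = rng.normal(scale=0.5, size=(2, 2))
            B = rng.normal(scale=0.5, size=(2, 2))
            z0, v_prev = rng.normal(size=2), rng.normal(size=2)
            ref = rng.normal(size=(10, 2))
            seq, _ = mm.mpc_solve(z0, ref, A, B, spec, v_prev=v_prev)
            c_opt = mpc_cost(z0, ref, A, B, spec, v_prev, seq)
            c_hold = mpc_cost(z0, ref, A, B, spec, v_prev,
                              np.tile(v_prev, (10, 1)))
            assert c_opt <= c_hold + 1e-12

    def test_huge_R_freezes_input_increments(self):
        spec = MpcSpec(R=1e6 * np.eye(2))
        A = np.array([[0.9, 0.0], [0.0, 0.8]])
        seq, _ = mm.mpc_solve(np.zeros(2), np.ones((10, 2)), A, np.eye(2),
                              spec, v_prev=np.array([0.3, -0.2]))
        dv = np.diff(np.vstack([[0.3, -0.2], seq]), axis=0)
        assert np.abs(dv).max() < 1e-4
        # and the increments shrink further as R grows
        seq8, _ = mm.mpc_solve(np.zeros(2), np.ones((10, 2)), A, np.eye(2),
                               MpcSpec(R=1e8 * np.eye(2)),
                               v_prev=np.array([0.3, -0.2]))
        dv8 = np.diff(np.vstack([[0.3, -0.2], seq8]), axis=0)
        assert np.abs(dv8).max() < np.abs(dv).max() / 10.0

    def test_window_of_length_T_plus_one_skips_current_row(self):
        A, B = np.eye(2) * 0.5, np.eye(2)
        ref_T = np.tile([1.0, 0.0], (10, 1))
        ref_T1 = np.vstack([[99.0, 99.0], ref_T])
        a, _ = mm.mpc_solve(np.zeros(2), ref_T, A, B)
        b, _ = mm.mpc_solve(np.zeros(2), ref_T1, A, B)
        np.testing.assert_allclose(a, b)

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            mm.mpc_solve(np.zeros(2), np.zeros((4, 2)), np.eye(2), np.eye(2))

    def test_input_bounds_respected(self):
        spec = MpcSpec(v_bounds=(np.array([-0.1, -0.1]), np.array([0.1, 0.1])))
        A = np.array([[0.9, 0.0], [0.0, 0.8]])
        seq, _ = mm.mpc_solve(np.zeros(2), np.ones((10, 2)) * 5.0, A,
                              np.eye(2), spec)
        assert seq.min() >= -0.1 - 1e-9 and seq.max() <= 0.1 + 1e-9

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            MpcSpec(R=np.zeros((2, 2)))              # not positive definite
        with pytest.raises(ValueError):
            MpcSpec(Q=np.array([[1.0, 2.0], [0.0, 1.0]]))  # asymmetric
        with pytest.raises(ValueError):
            MpcSpec(horizon=0)


class TestRecedingHorizonController:
    def test_matches_single_solve_and_carries_v_prev(self):
        A = np.array([[0.9, 0.05], [0.0, 0.85]])
        B = np.eye(2) * 0.2
        ctrl = mm.MpcController(A, B)
        ref = np.tile([1.0, -1.0], (10, 1))
        v1 = ctrl(np.zeros(2), ref)
        _, expect1 = mm.mpc_solve(np.zeros(2), ref, A, B, v_prev=np.zeros(2))
        np.testing.assert_allclose(v1, expect1, atol=1e-10)
        z1 = A @ np.zeros(2) + B @ v1
        v2 = ctrl(z1, ref)
        _, expect2 = mm.mpc_solve(z1, ref, A, B, v_prev=v1)
        np.testing.assert_allclose(v2, expect2, atol=1e-10)

    def test_closed_loop_offset_free_tracking(self):
        """On the exact 2-D linear plant with a reachable constant
        reference, receding-horizon MPC drives the error to zero."""
        A = np.array([[0.95, 0.03], [0.0, 0.92]])
        B = np.array([[0.05, 0.01], [0.0, 0.05]])
        ctrl = mm.MpcController(A, B)
        z = np.zeros(2)
        target = np.array([1.0, -0.5])
        ref = np.tile(target, (10, 1))
        for _ in range(50):
            v = ctrl(z, ref)
            z = A @ z + B @ v
        assert np.linalg.norm(z - target) < 1e-3
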