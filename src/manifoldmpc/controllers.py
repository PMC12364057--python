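"""Latent-space controllers: discrete PID and receding-horizon MPC.

PID computes the latent input from present and past tracking errors,

    v = K_P e + K_I * sum(e) * dt + K_D * (e - e_prev) / dt

with 2x2 gain matrices and dt = 1 step (finite-difference discretization
of the continuous controller).

MPC minimizes, over the input sequence v_0..v_{T-1}, the quadratic cost

    J = e_T' S e_T + sum_{i=1}^{T-1} e_i' Q e_i + sum_{i=0}^{T-1} dv_i' R dv_i

subject to z_{i+1} = A z_i + B v_i, where e_i = z_i - z*_i is the tracking
error and dv_i = v_i - v_{i-1} with v_{-1} the last input actually applied
(carried across receding-horizon iterations). Because the dynamics are
linear and the cost quadratic, the unconstrained problem condenses to a
dense positive-definite linear solve; only the first optimized input is
applied, and the problem is re-solved from the new measured state at the
next step. Defaults follow the set-point experiments: horizon T = 10,
Q = S = I, R = 0.001 * I, no state or input bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "PidGains", "PidState", "default_pid_gains", "pid_step", "PidController",
    "MpcSpec", "default_mpc_spec", "mpc_solve", "MpcController",
    "MpcSolverError",
]


# ---------------------------------------------------------------------
# PID
# ---------------------------------------------------------------------

@dataclass
class PidGains:
    K_P: np.ndarray
    K_I: np.ndarray
    K_D: np.ndarray
    integral_bound: float | None = None   # optional anti-windup clip

    def __post_init__(self):
        self.K_P = np.atleast_2d(np.asarray(self.K_P, dtype=np.float64))
        self.K_I = np.atleast_2d(np.asarray(self.K_I, dtype=np.float64))
        self.K_D = np.atleast_2d(np.asarray(self.K_D, dtype=np.float64))
        for K in (self.K_P, self.K_I, self.K_D):
            if not np.isfinite(K).all():
                raise ValueError("gain matrices must be finite")


def default_pid_gains() -> PidGains:
    """Gain matrices used in all set-point and trajectory experiments."""
    return PidGains(
        K_P=np.array([[20.0, 20.0], [5.0, 20.0]]),
        K_I=np.array([[0.9, 0.9], [0.1, 0.1]]),
        K_D=np.array([[0.01, 0.01], [0.01, 0.01]]),
    )


@dataclass
class PidState:
    integral: np.ndarray = field(default_factory=lambda: np.zeros(2))
    prev_error: np.ndarray = field(default_factory=lambda: np.zeros(2))
    dt: float = 1.0


def pid_step(error: np.ndarray, state: PidState, gains: PidGains
             ) -> tuple[np.ndarray, PidState]:
    """One discrete PID update; returns the latent input and new state.

    The integral accumulator includes the current error; the derivative is
    the backward difference against the previous error.
    """
    e = np.asarray(error, dtype=np.float64)
    integral = state.integral + e * state.dt
    if gains.integral_bound is not None:
        integral = np.clip(integral, -gains.integral_bound, gains.integral_bound)
    v = (gains.K_P @ e + gains.K_I @ integral
         + gains.K_D @ ((e - state.prev_error) / state.dt))
    return v, PidState(integral=integral, prev_error=e.copy(), dt=state.dt)


class PidController:
    """Stateful wrapper used by the closed-loop runner."""

    def __init__(self, gains: PidGains | None = None):
        self.gains = gains if gains is not None else default_pid_gains()
        self.reset()

    def reset(self) -> None:
        k = self.gains.K_P.shape[1]
        self.state = PidState(integral=np.zeros(k), prev_error=np.zeros(k))

    def __call__(self, z: np.ndarray, reference_window: np.ndarray) -> np.ndarray:
        error = reference_window[0] - np.asarray(z)
        v, self.state = pid_step(error, self.state, self.gains)
        return v


# ---------------------------------------------------------------------
# MPC
# ---------------------------------------------------------------------

class MpcSolverError(RuntimeError):
    """Raised when the constrained solver fails; carries the status."""

    def __init__(self, status):
        super().__init__(f"MPC solve failed: {status}")
        self.status = status


@dataclass
class MpcSpec:
    horizon: int = 10
    Q: np.ndarray = field(default_factory=lambda: np.eye(2))
    R: np.ndarray = field(default_factory=lambda: 0.001 * np.eye(2))
    S: np.ndarray = field(default_factory=lambda: np.eye(2))
    v_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=np.float64))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=np.float64))
        self.S = np.atleast_2d(np.asarray(self.S, dtype=np.float64))
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for M, name in ((self.Q, "Q"), (self.S, "S"), (self.R, "R")):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
        if np.linalg.eigvalsh(self.R).min() <= 0:
            raise ValueError("R must be positive definite")
        if (np.linalg.eigvalsh(self.Q).min() < -1e-12
                or np.linalg.eigvalsh(self.S).min() < -1e-12):
            raise ValueError("Q and S must be positive semidefinite")


def default_mpc_spec() -> MpcSpec:
    """Protocol defaults: T = 10, Q = S = I, R = 0.001 I, no bounds."""
    return MpcSpec()


def _condense(A: np.ndarray, B: np.ndarray, spec: MpcSpec):
    """Stack the T-step dynamics: e_{1..T} = Phi z0 + Gamma V - Zref."""
    T = spec.horizon
    k, m = B.shape
    powers = [np.eye(k)]
    for _ in range(T):
        powers.append(A @ powers[-1])
    Phi = np.vstack([powers[i] for i in range(1, T + 1)])        # (T*k, k)
    Gamma = np.zeros((T * k, T * m))
    for i in range(1, T + 1):
        for j in range(i):
            Gamma[(i - 1) * k:i * k, j * m:(j + 1) * m] = powers[i - 1 - j] @ B
    Wblocks = [spec.Q] * (T - 1) + [spec.S]
    W = np.zeros((T * k, T * k))
    for i, Qi in enumerate(Wblocks):
        W[i * k:(i + 1) * k, i * k:(i + 1) * k] = Qi
    D = np.eye(T * m)
    for i in range(1, T):
        D[i * m:(i + 1) * m, (i - 1) * m:i * m] = -np.eye(m)
    Rbar = np.kron(np.eye(T), spec.R)
    return Phi, Gamma, W, D, Rbar


def mpc_solve(z0: np.ndarray, reference: np.ndarray, A: np.ndarray,
              B: np.ndarray, spec: MpcSpec | None = None,
              v_prev: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Solve one receding-horizon problem.

    ``reference`` supplies the targets z*_1..z*_T (shape (T, k); a window of
    length T+1 may be passed, in which case the first row is the current
    reference and is skipped -- the current error is not influenced by the
    decision variables). Returns (input sequence v_0..v_{T-1}, first input).
    """
    spec = spec if spec is not None else default_mpc_spec()
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    z0 = np.asarray(z0, dtype=np.float64)
    T = spec.horizon
    k, m = B.shape
    ref = np.atleast_2d(np.asarray(reference, dtype=np.float64))
    if len(ref) == T + 1:
        ref = ref[1:]
    if len(ref) < T:
        raise ValueError(f"reference window must provide at least T={T} targets")
    ref = ref[:T]
    v_prev = np.zeros(m) if v_prev is None else np.asarray(v_prev, dtype=np.float64)

    Phi, Gamma, W, D, Rbar = _condense(A, B, spec)
    c = Phi @ z0 - ref.reshape(-1)                   # error offset, e = c + Gamma V
    d = np.zeros(T * m)
    d[:m] = -v_prev                                  # dv = D V + d
    H = Gamma.T @ W @ Gamma + D.T @ Rbar @ D
    g = Gamma.T @ W @ c + D.T @ Rbar @ d

    if spec.v_bounds is None:
        V = np.linalg.solve(H, -g)
    else:
        lo, hi = spec.v_bounds
        if np.any(np.asarray(lo) > np.asarray(hi)):
            raise MpcSolverError("infeasible input bounds")
        bounds = [(lo[i % m], hi[i % m]) for i in range(T * m)]
        res = minimize(lambda x: 0.5 * x @ H @ x + g @ x,
                       np.zeros(T * m), jac=lambda x: H @ x + g,
                       method="L-BFGS-B", bounds=bounds)
        if not res.success:
            raise MpcSolverError(res.message)
        V = res.x
    seq = V.reshape(T, m)
    return seq, seq[0].copy()


def mpc_cost(z0, reference, A, B, spec, v_prev, V_seq) -> float:
    """Cost of an explicit input sequence (diagnostics / optimality checks)."""
    spec = spec if spec is not None else default_mpc_spec()
    T = spec.horizon
    ref = np.atleast_2d(reference)
    if len(ref) == T + 1:
        ref = ref[1:]
    z = np.asarray(z0, dtype=np.float64).copy()
    vp = np.zeros(B.shape[1]) if v_prev is None else np.asarray(v_prev)
    cost = 0.0
    for i in range(T):
        dv = V_seq[i] - vp
        cost += float(dv @ spec.R @ dv)
        z = A @ z + B @ V_seq[i]
        e = z - ref[i]
        Wi = spec.S if i == T - 1 else spec.Q
        cost += float(e @ Wi @ e)
        vp = V_seq[i]
    return cost


class MpcController:
    """Receding-horizon controller carrying the last applied input."""

    def __init__(self, A: np.ndarray, B: np.ndarray, spec: MpcSpec | None = None):
        self.A = np.atleast_2d(np.asarray(A, dtype=np.float64))
        self.B = np.atleast_2d(np.asarray(B, dtype=np.float64))
        self.spec = spec if spec is not None else default_mpc_spec()
        # condensed matrices depend only on (A, B, spec): precompute once
        Phi, Gamma, W, D, Rbar = _condense(self.A, self.B, self.spec)
        self._Phi, self._Gamma, self._W = Phi, Gamma, W
        self._D, self._Rbar = D, Rbar
        self._H = Gamma.T @ W @ Gamma + D.T @ Rbar @ D
        self._H_inv = np.linalg.inv(self._H) if self.spec.v_bounds is None else None
        self.reset()

    def reset(self) -> None:
        self.v_prev = np.zeros(self.B.shape[1])

    def __call__(self, z: np.ndarray, reference_window: np.ndarray) -> np.ndarray:
        """Solve from the measured state; apply and remember the first input.

        ``reference_window`` holds z*_{n..n+T} (or z*_{n+1..n+T}); rows
        beyond the available reference should be padded by the caller.
        """
        spec, T = self.spec, self.spec.horizon
        m = self.B.shape[1]
        ref = np.atleast_2d(reference_window)
        if len(ref) == T + 1:
            ref = ref[1:]
        ref = ref[:T]
        if self._H_inv is not None:
            c = self._Phi @ np.asarray(z, dtype=np.float64) - ref.reshape(-1)
            d = np.zeros(T * m)
            d[:m] = -self.v_prev
            g = self._Gamma.T @ (self._W @ c) + self._D.T @ (self._Rbar @ d)
            v = (self._H_inv @ -g)[:m]
        else:
            _, v = mpc_solve(z, ref, self.A, self.B, spec, self.v_prev)
        self.v_prev = v.copy()
        return v
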