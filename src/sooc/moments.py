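"""Mean/covariance propagation for open-loop-controlled stochastic plants.

For a bilinear SDE

    dx = [(A + sum_i N_i u_i(t)) x + B u(t)] dt + G(u(t), t) dw

with a deterministic (open-loop) control u(t), the state is a Gaussian
process and its first two moments obey closed ordinary differential
equations,

    m' = (A + sum_i N_i u_i) m + B u,
    P' = (A + sum_i N_i u_i) P + P (A + sum_i N_i u_i)^T + G G^T,

which this module propagates exactly.  For a general nonlinear drift f the
same structure holds approximately under Gaussian statistical linearization,

    m' = f(m, u, t),    P' = F P + P F^T + E[G G^T],  F = df/dx(m, u, t),

with E[G G^T] = G(u,t) G(u,t)^T whenever the diffusion is state-independent;
state-dependent diffusions are closed by evaluating G at the mean (an
approximation, flagged as such).

Expected quadratic costs of the original stochastic problem reduce to
deterministic functionals of (m, P, u); :func:`expected_cost` evaluates that
reduction with a trapezoidal quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from ._symbolic import SymbolicDynamics, unvech, vech

__all__ = [
    "StateMoments",
    "MomentPath",
    "BilinearSystem",
    "NonlinearPlant",
    "QuadraticCost",
    "CostBreakdown",
    "propagate_moments_bilinear",
    "propagate_moments_linearized",
    "expected_cost",
    "diffusion_outer",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


class ValidationError(ValueError):
    """Raised for ill-posed numerical inputs (non-PSD covariance, grids...)."""


class ConfigurationError(ValueError):
    """Raised for dimension mismatches and unsupported configurations."""


@dataclass(frozen=True)
class StateMoments:
    """First two moments of the state at one instant."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        n = mean.shape[0]
        if cov.shape != (n, n):
            raise ConfigurationError(
                f"cov shape {cov.shape} does not match mean dim {n}"
            )
        if not np.allclose(cov, cov.T, atol=_SYM_TOL):
            raise ValidationError("covariance is not symmetric")
        w = np.linalg.eigvalsh(cov)
        if w.min(initial=0.0) < -_PSD_TOL:
            raise ValidationError(
                f"covariance has eigenvalue {w.min():.3e} < -{_PSD_TOL}"
            )

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


class MomentPath(Sequence):
    """Moment trajectory on a time grid; behaves as a sequence of
    :class:`StateMoments`."""

    def __init__(self, t: np.ndarray, mean: np.ndarray, cov: np.ndarray):
        self.t = np.asarray(t, dtype=float)
        self.mean = np.asarray(mean, dtype=float)
        self.cov = np.asarray(cov, dtype=float)

    def __len__(self):
        return len(self.t)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return MomentPath(self.t[i], self.mean[i], self.cov[i])
        return StateMoments(self.mean[i], self.cov[i])

    @property
    def final(self) -> StateMoments:
        return self[-1]


@dataclass
class BilinearSystem:
    """Matrices of a bilinear SDE: drift (A + sum N_i u_i) x + B u,
    diffusion G.

    ``diffusion`` may be a constant (n, m) array or a sympy Matrix in the
    control symbols ``u_syms`` (signal-dependent noise).
    """

    A: np.ndarray
    B: np.ndarray
    N: Sequence[np.ndarray]
    diffusion: object
    u_syms: tuple = ()
    name: str = "bilinear"

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.N = [np.asarray(Ni, dtype=float) for Ni in self.N]
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ConfigurationError("A must be square")
        if self.B.ndim != 2 or self.B.shape[0] != n:
            raise ConfigurationError("B must be n x p")
        p = self.B.shape[1]
        if len(self.N) not in (0, p):
            raise ConfigurationError("need one N_i per control (or none)")
        for Ni in self.N:
            if Ni.shape != (n, n):
                raise ConfigurationError("each N_i must be n x n")
        self.n = n
        self.p = p

    @property
    def dynamics(self) -> SymbolicDynamics:
        if not hasattr(self, "_dynamics"):
            u = self.u_syms or sp.symbols(f"u0:{self.p}", real=True)
            x = sp.symbols(f"x0:{self.n}", real=True)
            xv = sp.Matrix(x)
            uv = sp.Matrix(u)
            Adrift = sp.Matrix(self.A)
            for Ni, ui in zip(self.N, u):
                Adrift = Adrift + sp.Matrix(Ni) * ui
            f = Adrift * xv + sp.Matrix(self.B) * uv
            G = self.diffusion
            if not isinstance(G, sp.MatrixBase):
                G = sp.Matrix(np.atleast_2d(np.asarray(G, dtype=float)))
                if G.shape[0] == 1 and self.n > 1:
                    G = G.T
            self._dynamics = SymbolicDynamics(self.name, x, u, f, G)
        return self._dynamics


@dataclass
class NonlinearPlant:
    """A plant defined by sympy drift/diffusion expressions.

    Exposes numeric ``drift``, ``drift_jacobian`` and ``diffusion``
    callables with signature (x, u, t); all are generated from the symbolic
    declaration, so the Jacobian is exact.
    """

    dynamics: SymbolicDynamics
    parameters: dict = field(default_factory=dict)
    control_bounds: tuple = (None, None)
    state_names: tuple = ()
    # optional extras used by plant-specific helpers
    torque_expr: object = None  # sympy Matrix tau(x, u), joint torques
    meta: dict = field(default_factory=dict)

    @property
    def state_dim(self) -> int:
        return self.dynamics.n

    @property
    def control_dim(self) -> int:
        return self.dynamics.p

    @property
    def name(self) -> str:
        return self.dynamics.name

    def drift(self, x, u, t=None):
        return self.dynamics.drift(x, u, t)

    def drift_jacobian(self, x, u, t=None):
        return self.dynamics.drift_jacobian(x, u, t)

    def diffusion(self, x, u, t=None):
        return self.dynamics.diffusion(x, u, t)


def _as_dynamics(plant_or_system) -> SymbolicDynamics:
    if isinstance(plant_or_system, SymbolicDynamics):
        return plant_or_system
    return plant_or_system.dynamics


def _control_interpolant(u_traj, t_grid, p):
    """Accept a callable t -> u or an array of node controls."""
    if callable(u_traj):
        return lambda t: np.atleast_1d(np.asarray(u_traj(t), dtype=float))
    U = np.asarray(u_traj, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    if U.shape != (len(t_grid), p):
        raise ConfigurationError(
            f"control trajectory shape {U.shape} != ({len(t_grid)}, {p})"
        )

    def interp(t):
        return np.array(
            [np.interp(t, t_grid, U[:, j]) for j in range(p)]
        )

    return interp


def _check_initial(dyn, m0, P0, t_grid):
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing, len >= 2")
    m0 = np.asarray(m0, dtype=float)
    P0 = np.atleast_2d(np.asarray(P0, dtype=float))
    if m0.shape != (dyn.n,) or P0.shape != (dyn.n, dyn.n):
        raise ConfigurationError(
            f"initial moments have wrong shape for state dim {dyn.n}"
        )
    StateMoments(m0, P0)  # validates symmetry / PSD
    return m0, P0, t_grid


def _propagate(dyn, u_traj, m0, P0, t_grid, method, rtol, atol):
    m0, P0, t_grid = _check_initial(dyn, m0, P0, t_grid)
    ufun = _control_interpolant(u_traj, t_grid, dyn.p)
    z0 = np.concatenate([m0, vech(P0)])

    if method == "rk45":
        sol = solve_ivp(
            lambda t, z: dyn.moment_rhs(z, ufun(t)),
            (t_grid[0], t_grid[-1]),
            z0,
            t_eval=t_grid,
            rtol=rtol,
            atol=atol,
            method="RK45",
        )
        if not sol.success:  # pragma: no cover - integrator failure
            raise ValidationError(f"moment integration failed: {sol.message}")
        Z = sol.y.T
    elif method == "rk4":
        # fixed-step classical Runge-Kutta on the given grid (the same
        # deterministic discretization family as the transcription)
        Z = np.empty((len(t_grid), dyn.nz))
        Z[0] = z0
        for k in range(len(t_grid) - 1):
            h = t_grid[k + 1] - t_grid[k]
            t = t_grid[k]
            z = Z[k]
            k1 = dyn.moment_rhs(z, ufun(t))
            k2 = dyn.moment_rhs(z + h / 2 * k1, ufun(t + h / 2))
            k3 = dyn.moment_rhs(z + h / 2 * k2, ufun(t + h / 2))
            k4 = dyn.moment_rhs(z + h * k3, ufun(t + h))
            Z[k + 1] = z + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    else:
        raise ConfigurationError(f"unknown integration method {method!r}")

    mean = Z[:, : dyn.n]
    cov = unvech(Z[:, dyn.n :], dyn.n)
    wmin = min(
        np.linalg.eigvalsh(cov[k]).min() for k in range(len(t_grid))
    )
    if wmin < -_PSD_TOL:
        raise ValidationError(
            f"propagated covariance lost PSD (min eig {wmin:.2e})"
        )
    return MomentPath(t_grid, mean, cov)


def propagate_moments_bilinear(
    system: BilinearSystem,
    u_traj,
    m0,
    P0,
    t_grid,
    method: str = "rk45",
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> MomentPath:
    """Exact moment propagation for a bilinear system (the state is a
    Gaussian process, so these ODEs are not an approximation)."""
    return _propagate(
        _as_dynamics(system), u_traj, m0, P0, t_grid, method, rtol, atol
    )


def propagate_moments_linearized(
    plant,
    u_traj,
    m0,
    P0,
    t_grid,
    method: str = "rk45",
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> MomentPath:
    """Gaussian statistical linearization: the covariance is driven by the
    drift Jacobian along the mean, exact whenever the drift is affine in
    the state."""
    return _propagate(
        _as_dynamics(plant), u_traj, m0, P0, t_grid, method, rtol, atol
    )


def diffusion_outer(plant_or_system, u, t=None, m=None) -> np.ndarray:
    """E[G G^T]: exact for state-independent diffusion, mean-evaluated
    (approximate) otherwise; requires ``m`` in the latter case."""
    dyn = _as_dynamics(plant_or_system)
    if dyn.diffusion_state_dependent and m is None:
        raise ValidationError(
            "state-dependent diffusion: a mean must be supplied "
            "(only the mean-evaluated closure is offered)"
        )
    x = np.zeros(dyn.n) if m is None else np.asarray(m, dtype=float)
    G = dyn.diffusion(x, np.asarray(u, dtype=float), t)
    return G @ G.T


def _check_psd(M, name, definite=False):
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if not np.allclose(M, M.T, atol=_SYM_TOL):
        raise ValidationError(f"{name} must be symmetric")
    if definite:
        try:
            np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            raise ValidationError(f"{name} must be positive definite")
    elif np.linalg.eigvalsh(M).min(initial=0.0) < -_PSD_TOL:
        raise ValidationError(f"{name} must be positive semidefinite")
    return M


@dataclass
class QuadraticCost:
    """Expected quadratic cost weights, optionally extended with general
    mean/covariance terms.

    The extras may be python callables -- ``extra_running(m, P, u)`` and
    ``extra_terminal(m_f, P_f)`` -- or sympy expressions in the plant's
    moment symbols (``dynamics.m_syms``, ``dynamics.P_syms``,
    ``dynamics.u``); symbolic extras are required by the transcription,
    which needs their derivatives.
    """

    R: np.ndarray
    Q: np.ndarray | None = None
    Qf: np.ndarray | None = None
    Qf_cov: np.ndarray | None = None   # weights the terminal covariance only
    extra_running: object = None
    extra_terminal: object = None

    def __post_init__(self):
        self.R = _check_psd(self.R, "R", definite=True)
        p = self.R.shape[0]
        self.p = p
        if self.Q is not None:
            self.Q = _check_psd(self.Q, "Q")
        if self.Qf is not None:
            self.Qf = _check_psd(self.Qf, "Qf")
        if self.Qf_cov is not None:
            self.Qf_cov = _check_psd(self.Qf_cov, "Qf_cov")


@dataclass
class CostBreakdown:
    effort: float
    mean_state: float
    covariance: float
    terminal_mean: float
    terminal_cov: float
    extra_running: float
    extra_terminal: float

    @property
    def total(self) -> float:
        return (
            self.effort
            + self.mean_state
            + self.covariance
            + self.terminal_mean
            + self.terminal_cov
            + self.extra_running
            + self.extra_terminal
        )


def _extra_callable(extra, dyn: SymbolicDynamics, terminal: bool):
    if extra is None:
        return None
    if callable(extra) and not isinstance(extra, sp.Basic):
        return extra
    args = tuple(dyn.m_syms) + tuple(dyn.P_syms)
    if not terminal:
        args = args + tuple(dyn.u)
    fn = sp.lambdify(args, extra, modules="numpy")
    r, c = np.triu_indices(dyn.n)

    def call(m, P, u=None):
        vals = list(np.asarray(m, dtype=float))
        vals += list(np.asarray(P, dtype=float)[r, c])
        if not terminal:
            vals += list(np.asarray(u, dtype=float))
        return float(fn(*vals))

    return call


def expected_cost(
    cost: QuadraticCost,
    moments: MomentPath | Sequence[StateMoments],
    u_traj,
    dynamics: SymbolicDynamics | None = None,
) -> CostBreakdown:
    """Deterministic reduction of the expected cost: trapezoidal quadrature
    of u'Ru + m'Qm + tr(QP) plus terminal m'Qf m + tr(Qf P) and any extras.
    """
    if not isinstance(moments, MomentPath):
        t = np.array([0.0])  # pragma: no cover - sequences carry no grid
        raise ConfigurationError("expected_cost requires a MomentPath")
    t = moments.t
    U = np.asarray(u_traj, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    if U.shape[0] != len(t):
        raise ValidationError("control and moment grids differ in length")
    if U.shape[1] != cost.R.shape[0]:
        raise ConfigurationError("control dim does not match R")

    effort = float(np.trapezoid(np.einsum("ki,ij,kj->k", U, cost.R, U), t))
    mean_state = cov_run = 0.0
    if cost.Q is not None:
        mean_state = float(
            np.trapezoid(
                np.einsum("ki,ij,kj->k", moments.mean, cost.Q, moments.mean),
                t,
            )
        )
        cov_run = float(
            np.trapezoid(np.einsum("ij,kji->k", cost.Q, moments.cov), t)
        )
    term_mean = term_cov = 0.0
    if cost.Qf is not None:
        mf = moments.mean[-1]
        term_mean = float(mf @ cost.Qf @ mf)
        term_cov = float(np.trace(cost.Qf @ moments.cov[-1]))
    if cost.Qf_cov is not None:
        term_cov += float(np.trace(cost.Qf_cov @ moments.cov[-1]))

    extra_run = extra_term = 0.0
    if cost.extra_running is not None:
        fn = _extra_callable(cost.extra_running, dynamics, terminal=False) \
            if dynamics is not None or isinstance(cost.extra_running, sp.Basic) \
            else cost.extra_running
        if isinstance(cost.extra_running, sp.Basic) and dynamics is None:
            raise ConfigurationError(
                "symbolic extra_running needs the plant dynamics"
            )
        vals = np.array(
            [fn(moments.mean[k], moments.cov[k], U[k]) for k in range(len(t))]
        )
        extra_run = float(np.trapezoid(vals, t))
    if cost.extra_terminal is not None:
        if isinstance(cost.extra_terminal, sp.Basic) and dynamics is None:
            raise ConfigurationError(
                "symbolic extra_terminal needs the plant dynamics"
            )
        fn = _extra_callable(cost.extra_terminal, dynamics, terminal=True) \
            if isinstance(cost.extra_terminal, sp.Basic) else cost.extra_terminal
        extra_term = float(fn(moments.mean[-1], moments.cov[-1]))

    return CostBreakdown(
        effort=effort,
        mean_state=mean_state,
        covariance=cov_run,
        terminal_mean=term_mean,
        terminal_cov=term_cov,
        extra_running=extra_run,
        extra_terminal=extra_term,
    )
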