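"""Direct transcription of the equivalent deterministic problem.

The stochastic open-loop problem is solved as a deterministic optimal
control problem over the moment state z = (m, vech P): node-wise controls
and moment states are the decision variables, trapezoidal defect
constraints encode the moment ODEs, and the objective is the reduced
expected cost.  All derivatives handed to the NLP solver are exact
(generated symbolically), which is what makes scipy's SQP methods converge
reliably on these problems.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sps
import sympy as sp
from scipy.optimize import Bounds, NonlinearConstraint, minimize

from ._symbolic import SymbolicDynamics, unvech, vech, vech_indices
from .moments import (
    BilinearSystem,
    ConfigurationError,
    CostBreakdown,
    MomentPath,
    QuadraticCost,
    expected_cost,
)
from .tasks import TaskSpec

__all__ = [
    "OCProblem",
    "SolverOptions",
    "MomentTrajectory",
    "TranscribedNLP",
    "build_equivalent_doc",
    "solve",
    "restart_stability_check",
]


@dataclass
class SolverOptions:
    n_nodes: int = 100
    scheme: str = "trapezoidal"
    nlp_tolerance: float = 1e-10
    max_iterations: int = 500
    method: str = "slsqp"           # "slsqp" | "trust-constr" | "hybrid"
    polish_iterations: int = 300    # SLSQP polish budget (hybrid only)
    objective_scaling: float | str = "auto"  # scale fed to the NLP solver
    # "propagate_cov": interpolate means, forward-propagate the covariance
    # "propagate_full": forward-propagate the whole moment state
    initial_guess_policy: str = "propagate_cov"
    # scalar, per-channel array, or callable t -> u
    guess_control: object = 0.01
    random_seed: int = 0
    jitter: float = 0.0

    def __post_init__(self):
        if self.n_nodes < 10:
            raise ConfigurationError("n_nodes must be >= 10")
        if self.nlp_tolerance <= 0:
            raise ConfigurationError("nlp_tolerance must be > 0")
        if self.scheme != "trapezoidal":
            raise ConfigurationError(
                f"unsupported transcription scheme {self.scheme!r}"
            )
        if self.method not in ("slsqp", "trust-constr", "hybrid"):
            raise ConfigurationError(f"unknown NLP method {self.method!r}")


@dataclass
class OCProblem:
    """Optimal control problem over the moments of a stochastic plant."""

    plant: object                       # NonlinearPlant or BilinearSystem
    cost: QuadraticCost
    t_f: float
    m0: np.ndarray
    P0: np.ndarray | None = None        # None only with terminal_cov="cyclic"
    terminal_mean: np.ndarray | None = None
    terminal_cov: str = "free"          # "free" | "cyclic"
    terminal_constraints: list = field(default_factory=list)
    control_bounds: tuple | None = None
    # states with no noise coupling whose covariance rows are structurally
    # zero (e.g. a deterministic reference subsystem); pinning them removes
    # flat directions from the NLP
    deterministic_states: tuple = ()
    name: str = ""

    def __post_init__(self):
        if self.t_f <= 0:
            raise ConfigurationError("t_f must be > 0")
        dyn = self.dynamics
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.m0.shape != (dyn.n,):
            raise ConfigurationError(
                f"m0 has dim {self.m0.shape}, state dim is {dyn.n}"
            )
        if self.terminal_cov not in ("free", "cyclic"):
            raise ConfigurationError(
                f"unsupported terminal_cov {self.terminal_cov!r}"
            )
        if self.P0 is None:
            if self.terminal_cov != "cyclic":
                raise ConfigurationError(
                    "P0 may be omitted only for cyclic tasks"
                )
        else:
            self.P0 = np.asarray(self.P0, dtype=float)
        if self.terminal_mean is not None:
            self.terminal_mean = np.asarray(self.terminal_mean, dtype=float)
            if self.terminal_mean.shape != (dyn.n,):
                raise ConfigurationError("terminal_mean has wrong dim")
        lb, ub = self._resolve_bounds()
        if np.any(lb > ub):
            raise ConfigurationError("control bounds: lower > upper")

    @property
    def dynamics(self) -> SymbolicDynamics:
        return self.plant.dynamics

    def _resolve_bounds(self):
        dyn = self.dynamics
        bounds = self.control_bounds
        if bounds is None:
            bounds = getattr(self.plant, "control_bounds", (None, None))
        lb, ub = bounds
        lb = np.full(dyn.p, -np.inf) if lb is None else np.asarray(lb, float)
        ub = np.full(dyn.p, np.inf) if ub is None else np.asarray(ub, float)
        return lb, ub

    @classmethod
    def from_task(cls, plant, task: TaskSpec, **overrides) -> "OCProblem":
        kwargs = dict(
            plant=plant,
            cost=task.cost,
            t_f=task.t_f,
            m0=task.m0,
            P0=task.P0,
            terminal_mean=task.terminal_mean,
            terminal_cov=task.terminal_cov,
            terminal_constraints=list(task.terminal_constraints),
            control_bounds=task.control_bounds,
            deterministic_states=tuple(task.deterministic_states),
            name=task.name,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class MomentTrajectory:
    """Solution bundle: open-loop control, moments, cost breakdown and
    solver diagnostics."""

    t_grid: np.ndarray
    u: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    cost_breakdown: CostBreakdown
    status: str                     # converged | max_iter | infeasible
    nlp_residual: float
    n_iterations: int
    solve_time: float
    objective: float
    problem: OCProblem | None = None
    options: SolverOptions | None = None

    @property
    def moments(self) -> MomentPath:
        return MomentPath(self.t_grid, self.mean, self.cov)

    def control_interpolant(self):
        t, U = self.t_grid, self.u

        def interp(s):
            return np.array(
                [np.interp(s, t, U[:, j]) for j in range(U.shape[1])]
            )

        return interp

    def to_frame(self) -> pd.DataFrame:
        n = self.mean.shape[1]
        r, c = vech_indices(n)
        data = {"t": self.t_grid}
        for j in range(self.u.shape[1]):
            data[f"u_{j + 1}"] = self.u[:, j]
        for i in range(n):
            data[f"m_{i + 1}"] = self.mean[:, i]
        for i, j in zip(r, c):
            data[f"P_{i + 1}{j + 1}"] = self.cov[:, i, j]
        return pd.DataFrame(data)

    def save(self, out_dir, extra_manifest: dict | None = None):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "trajectory.csv", index=False)
        schema = (
            "trajectory.csv columns: t [s]; u_j (controls, node values); "
            "m_i (state means); P_ij (covariance, upper triangle row-major)."
        )
        (out / "trajectory.schema.txt").write_text(schema + "\n")
        manifest = {
            "status": self.status,
            "objective": self.objective,
            "nlp_residual": self.nlp_residual,
            "n_iterations": self.n_iterations,
            "solve_time_s": self.solve_time,
            "cost_breakdown": vars(self.cost_breakdown),
            "problem": self.problem.name if self.problem else "",
            "options": vars(self.options) if self.options else {},
        }
        if extra_manifest:
            manifest.update(extra_manifest)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float) + "\n"
        )
        return out


class TranscribedNLP:
    """The assembled nonlinear program (trapezoidal collocation)."""

    def __init__(self, problem: OCProblem, options: SolverOptions):
        self.problem = problem
        self.options = options
        dyn = problem.dynamics
        self.dyn = dyn
        N = options.n_nodes
        self.N = N
        self.nz = dyn.nz
        self.p = dyn.p
        self.blk = self.nz + self.p
        self.nw = N * self.blk
        self.t_grid = np.linspace(0.0, problem.t_f, N)
        self.h = self.t_grid[1] - self.t_grid[0]
        self.n_defects = (N - 1) * self.nz
        self._build_cost_functions()
        self._build_terminal_constraints()
        self._build_bounds()
        self._build_sparsity()

    # ---- symbolic cost ----------------------------------------------------

    def _moment_args(self):
        dyn = self.dyn
        return tuple(dyn.m_syms) + tuple(dyn.P_syms) + tuple(dyn.u)

    def _build_cost_functions(self):
        dyn = self.dyn
        cost = self.problem.cost
        if cost.R.shape[0] != dyn.p:
            raise ConfigurationError("cost R does not match control dim")
        m = sp.Matrix(dyn.m_syms)
        P = dyn.P_matrix
        u = sp.Matrix(dyn.u)
        L = (u.T * sp.Matrix(cost.R) * u)[0, 0]
        if cost.Q is not None:
            Q = sp.Matrix(cost.Q)
            L = L + (m.T * Q * m)[0, 0] + sp.trace(Q * P)
        if cost.extra_running is not None:
            if not isinstance(cost.extra_running, sp.Basic):
                raise ConfigurationError(
                    "transcription needs a symbolic extra_running term"
                )
            L = L + cost.extra_running
        T = sp.S.Zero
        if cost.Qf is not None:
            Qf = sp.Matrix(cost.Qf)
            T = T + (m.T * Qf * m)[0, 0] + sp.trace(Qf * P)
        if cost.Qf_cov is not None:
            T = T + sp.trace(sp.Matrix(cost.Qf_cov) * P)
        if cost.extra_terminal is not None:
            if not isinstance(cost.extra_terminal, sp.Basic):
                raise ConfigurationError(
                    "transcription needs a symbolic extra_terminal term"
                )
            T = T + cost.extra_terminal
        args = self._moment_args()
        nzp = self.nz + self.p
        from ._symbolic import _lambdify_vec

        self._L_fn = _lambdify_vec(args, [L], (1,))
        self._Lgrad_fn = _lambdify_vec(
            args, [sp.diff(L, a) for a in args], (nzp,)
        )
        self._T_fn = _lambdify_vec(args, [T], (1,))
        self._Tgrad_fn = _lambdify_vec(
            args, [sp.diff(T, a) for a in args], (nzp,)
        )

    def _build_terminal_constraints(self):
        exprs = self.problem.terminal_constraints
        self.n_terminal = len(exprs)
        if not exprs:
            self._tc_fn = self._tc_jac = None
            return
        args = self._moment_args()
        from ._symbolic import _lambdify_vec

        self._tc_fn = _lambdify_vec(args, list(exprs), (self.n_terminal,))
        J = sp.Matrix(exprs).jacobian(list(args))
        self._tc_jac = _lambdify_vec(
            args, [e for row in J.tolist() for e in row],
            (self.n_terminal, self.nz + self.p),
        )

    # ---- layout -----------------------------------------------------------

    def split(self, w):
        W = w.reshape(self.N, self.blk)
        return W[:, : self.nz], W[:, self.nz :]

    def _cols(self, Z, U):
        return [Z[:, i] for i in range(self.nz)] + [
            U[:, i] for i in range(self.p)
        ]

    def _build_sparsity(self):
        N, nz, blk = self.N, self.nz, self.blk
        nzk = len(self._keep_rows)
        self.nzk = nzk
        i = np.arange(nzk)[:, None]
        j = np.arange(blk)[None, :]
        rows_blk = np.broadcast_to(i, (nzk, blk))
        k = np.arange(N - 1)[:, None, None]
        self._def_rows = np.concatenate(
            [(k * nzk + rows_blk).ravel(), (k * nzk + rows_blk).ravel()]
        )
        cols_blk = np.broadcast_to(j, (nzk, blk))
        cols_k = (k * blk + cols_blk).ravel()
        cols_k1 = ((k + 1) * blk + cols_blk).ravel()
        self._def_cols = np.concatenate([cols_k, cols_k1])
        # identity pattern E = [I | 0] row-selected per interval
        E = np.zeros((nz, blk))
        E[:, :nz] = np.eye(nz)
        self._E = E[self._keep_rows]
        self.n_defects = (N - 1) * nzk
        n_extra = self.n_terminal + (
            len(self._stochastic_tri)
            if self.problem.terminal_cov == "cyclic"
            else 0
        )
        self.n_constraints = self.n_defects + n_extra

    def _build_bounds(self):
        pr, dyn = self.problem, self.dyn
        lbu, ubu = pr._resolve_bounds()
        lb = np.full((self.N, self.blk), -np.inf)
        ub = np.full((self.N, self.blk), np.inf)
        lb[:, self.nz :] = lbu
        ub[:, self.nz :] = ubu
        lb[0, : dyn.n] = ub[0, : dyn.n] = pr.m0
        if pr.P0 is not None:
            p0 = vech(pr.P0)
            lb[0, dyn.n : dyn.nz] = ub[0, dyn.n : dyn.nz] = p0
        if pr.terminal_mean is not None:
            lb[-1, : dyn.n] = ub[-1, : dyn.n] = pr.terminal_mean
        det = set(pr.deterministic_states)
        r, c = vech_indices(dyn.n)
        self._stochastic_tri = np.array(
            [k for k, (i, j) in enumerate(zip(r, c))
             if i not in det and j not in det],
            dtype=int,
        )
        if det:
            pinned = [k for k in range(dyn.ntri)
                      if k not in set(self._stochastic_tri)]
            for k in pinned:
                lb[:, dyn.n + k] = ub[:, dyn.n + k] = 0.0
        # defect rows for pinned covariance entries are identically 0 = 0;
        # they must be dropped or the SQP's equality set is rank-deficient
        self._keep_rows = np.concatenate(
            [np.arange(dyn.n), dyn.n + self._stochastic_tri]
        )
        self.lb, self.ub = lb.ravel(), ub.ravel()
        self.n_fixed = int(np.sum(self.lb == self.ub))
        self.n_free_variables = self.nw - self.n_fixed

    # ---- NLP callbacks ----------------------------------------------------

    def objective(self, w):
        Z, U = self.split(w)
        Lv = self._L_fn(*self._cols(Z, U))[:, 0]
        wgt = np.full(self.N, self.h)
        wgt[0] = wgt[-1] = self.h / 2
        Tv = self._T_fn(*self._cols(Z[-1:], U[-1:]))[0, 0]
        return float(Lv @ wgt + Tv)

    def objective_grad(self, w):
        Z, U = self.split(w)
        g = self._Lgrad_fn(*self._cols(Z, U))
        wgt = np.full(self.N, self.h)
        wgt[0] = wgt[-1] = self.h / 2
        g = g * wgt[:, None]
        g[-1] += self._Tgrad_fn(*self._cols(Z[-1:], U[-1:]))[0]
        return g.ravel()

    def constraints(self, w):
        Z, U = self.split(w)
        R = self.dyn.moment_rhs(Z, U)
        d = (Z[1:] - Z[:-1] - self.h / 2 * (R[1:] + R[:-1]))
        d = d[:, self._keep_rows].ravel()
        parts = [d]
        if self.problem.terminal_cov == "cyclic":
            sel = self.dyn.n + self._stochastic_tri
            parts.append(Z[0, sel] - Z[-1, sel])
        if self._tc_fn is not None:
            parts.append(self._tc_fn(*self._cols(Z[-1:], U[-1:]))[0])
        return np.concatenate(parts)

    def constraints_jac(self, w):
        Z, U = self.split(w)
        J = self.dyn.moment_rhs_jac(Z, U)[:, self._keep_rows, :]
        A = -self.h / 2 * J[:-1] - self._E
        B = -self.h / 2 * J[1:] + self._E
        vals = np.concatenate([A.ravel(), B.ravel()])
        rows, cols, data = [self._def_rows], [self._def_cols], [vals]
        row0 = self.n_defects
        dyn = self.dyn
        if self.problem.terminal_cov == "cyclic":
            sel = dyn.n + self._stochastic_tri
            nc = len(sel)
            idx = np.arange(nc)
            rows.append(np.concatenate([row0 + idx, row0 + idx]))
            cols.append(
                np.concatenate([sel, (self.N - 1) * self.blk + sel])
            )
            data.append(np.concatenate([np.ones(nc), -np.ones(nc)]))
            row0 += nc
        if self._tc_jac is not None:
            Jt = self._tc_jac(*self._cols(Z[-1:], U[-1:]))[0]
            r = np.repeat(np.arange(self.n_terminal), self.blk) + row0
            c = np.tile(
                (self.N - 1) * self.blk + np.arange(self.blk),
                self.n_terminal,
            )
            rows.append(r)
            cols.append(c)
            data.append(Jt.ravel())
        return sps.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_constraints, self.nw),
        ).tocsr()

    # ---- initial guess ----------------------------------------------------

    def initial_guess(self, rng: np.random.Generator | None = None):
        pr, dyn, N = self.problem, self.dyn, self.N
        lbu, ubu = pr._resolve_bounds()
        guess = self.options.guess_control
        if callable(guess):
            U = np.array([np.atleast_1d(guess(t)) for t in self.t_grid],
                         dtype=float)
        else:
            U = np.tile(np.broadcast_to(np.asarray(guess, dtype=float),
                                        (dyn.p,)), (N, 1))
        U = np.clip(U, lbu, ubu)
        if rng is not None and self.options.jitter > 0:
            U = U * (1 + self.options.jitter * rng.standard_normal(U.shape))
            U = np.clip(U, lbu, ubu)
        mf = pr.terminal_mean if pr.terminal_mean is not None else pr.m0
        Zm = np.stack(
            [
                np.interp(self.t_grid, [0, pr.t_f], [pr.m0[i], mf[i]])
                for i in range(dyn.n)
            ],
            axis=1,
        )
        P0 = pr.P0 if pr.P0 is not None else np.zeros((dyn.n, dyn.n))
        Z = np.zeros((N, dyn.nz))
        Z[:, : dyn.n] = Zm
        z = np.concatenate([pr.m0, vech(P0)])
        Z[0] = z
        h = self.h
        full = self.options.initial_guess_policy == "propagate_full"
        for k in range(N - 1):
            f = lambda zz, uu: self.dyn.moment_rhs(zz, uu)
            um = 0.5 * (U[k] + U[k + 1])
            k1 = f(z, U[k])
            k2 = f(z + h / 2 * k1, um)
            k3 = f(z + h / 2 * k2, um)
            k4 = f(z + h * k3, U[k + 1])
            z = z + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            # unstable plants blow the propagated guess up exponentially;
            # a clipped guess is still feasible enough for the SQP
            z = np.clip(z, -1e3, 1e3)
            if full:
                Z[k + 1] = z
            else:
                Z[k + 1, dyn.n :] = z[dyn.n :]
                z[: dyn.n] = Zm[k + 1]
        w0 = np.column_stack([Z, U]).ravel()
        return np.clip(w0, self.lb, self.ub)


def build_equivalent_doc(
    problem: OCProblem, options: SolverOptions | None = None
) -> TranscribedNLP:
    """Assemble the transcription without solving it."""
    return TranscribedNLP(problem, options or SolverOptions())


def _status_from(res, method, residual, tol) -> str:
    if method == "slsqp":
        if res.status == 0:
            status = "converged"
        elif res.status == 9:
            status = "max_iter"
        else:
            status = "infeasible"
    else:
        status = {1: "converged", 2: "converged", 0: "max_iter"}.get(
            res.status, "infeasible"
        )
    if status == "converged" and residual > max(1e-6, 100 * tol):
        status = "infeasible"
    return status


def solve(
    problem: OCProblem,
    options: SolverOptions | None = None,
    initial_guess: np.ndarray | None = None,
) -> MomentTrajectory:
    """Solve the transcribed problem.  Non-convergence is reported through
    ``status`` (with the best iterate returned), never raised."""
    options = options or SolverOptions()
    nlp = build_equivalent_doc(problem, options)
    rng = (
        np.random.default_rng(options.random_seed)
        if options.jitter > 0
        else None
    )
    w0 = initial_guess if initial_guess is not None else nlp.initial_guess(rng)

    if options.objective_scaling == "auto":
        # SQP line searches misbehave on badly-scaled objectives; normalize
        # by the guess objective so ftol acts on a O(1) quantity
        scale = 1.0 / max(1.0, abs(nlp.objective(w0)))
    else:
        scale = float(options.objective_scaling)

    t0 = time.time()
    status_method = options.method
    if options.method == "hybrid":
        # interior-point exploration followed by an SQP polish; the former
        # navigates poor guesses, the latter certifies a KKT point
        con = NonlinearConstraint(
            nlp.constraints, 0.0, 0.0, jac=nlp.constraints_jac
        )
        pre = minimize(
            lambda w: scale * nlp.objective(w),
            w0,
            jac=lambda w: scale * nlp.objective_grad(w),
            method="trust-constr",
            bounds=Bounds(nlp.lb, nlp.ub),
            constraints=[con],
            options={
                "maxiter": options.max_iterations,
                "gtol": max(options.nlp_tolerance, 1e-8),
                "xtol": 1e-14,
            },
        )
        cons = [
            {
                "type": "eq",
                "fun": nlp.constraints,
                "jac": lambda w: nlp.constraints_jac(w).toarray(),
            }
        ]
        res = minimize(
            lambda w: scale * nlp.objective(w),
            pre.x,
            jac=lambda w: scale * nlp.objective_grad(w),
            method="SLSQP",
            bounds=Bounds(nlp.lb, nlp.ub),
            constraints=cons,
            options={
                "maxiter": options.polish_iterations,
                "ftol": options.nlp_tolerance,
            },
        )
        status_method = "slsqp"
        if res.fun > pre.fun and np.max(
            np.abs(nlp.constraints(pre.x))
        ) < max(1e-6, np.max(np.abs(nlp.constraints(res.x)))):
            res = pre  # polish went backwards; keep the interior-point end
            status_method = "trust-constr"
            n_iter = pre.niter
        else:
            n_iter = pre.niter + res.nit
    elif options.method == "slsqp":
        cons = [
            {
                "type": "eq",
                "fun": nlp.constraints,
                "jac": lambda w: nlp.constraints_jac(w).toarray(),
            }
        ]
        res = minimize(
            lambda w: scale * nlp.objective(w),
            w0,
            jac=lambda w: scale * nlp.objective_grad(w),
            method="SLSQP",
            bounds=Bounds(nlp.lb, nlp.ub),
            constraints=cons,
            options={
                "maxiter": options.max_iterations,
                "ftol": options.nlp_tolerance,
            },
        )
        n_iter = res.nit
        status_method = "slsqp"
    else:
        con = NonlinearConstraint(
            nlp.constraints, 0.0, 0.0, jac=nlp.constraints_jac
        )
        res = minimize(
            lambda w: scale * nlp.objective(w),
            w0,
            jac=lambda w: scale * nlp.objective_grad(w),
            method="trust-constr",
            bounds=Bounds(nlp.lb, nlp.ub),
            constraints=[con],
            options={
                "maxiter": options.max_iterations,
                "gtol": options.nlp_tolerance,
                "xtol": 1e-14,
            },
        )
        n_iter = res.niter
        status_method = "trust-constr"
    dt = time.time() - t0

    Z, U = nlp.split(res.x)
    dyn = problem.dynamics
    mean = Z[:, : dyn.n]
    cov = unvech(Z[:, dyn.n :], dyn.n)
    residual = float(np.max(np.abs(nlp.constraints(res.x))))
    status = _status_from(res, status_method, residual, options.nlp_tolerance)
    path = MomentPath(nlp.t_grid, mean, cov)
    breakdown = expected_cost(problem.cost, path, U, dynamics=dyn)
    return MomentTrajectory(
        t_grid=nlp.t_grid,
        u=U,
        mean=mean,
        cov=cov,
        cost_breakdown=breakdown,
        status=status,
        nlp_residual=residual,
        n_iterations=int(n_iter),
        solve_time=dt,
        objective=float(res.fun) / scale,
        problem=problem,
        options=options,
    )


def restart_stability_check(
    problem: OCProblem,
    options: SolverOptions | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> dict:
    """Re-solve from jittered initial guesses and report the relative
    spread of converged optimal costs (a multimodality flag)."""
    if n_restarts < 2:
        raise ConfigurationError("n_restarts must be >= 2")
    base = options or SolverOptions()
    costs, statuses = [], []
    for i in range(n_restarts):
        opts = SolverOptions(**{**vars(base), "jitter": max(base.jitter, 0.25),
                                "random_seed": seed + i})
        traj = solve(problem, opts)
        statuses.append(traj.status)
        if traj.status != "infeasible":
            costs.append(traj.objective)
    if not costs:
        return {"statuses": statuses, "spread": np.nan, "costs": []}
    lo, hi = min(costs), max(costs)
    spread = (hi - lo) / max(abs(lo), 1e-300)
    return {
        "statuses": statuses,
        "costs": costs,
        "spread": float(spread),
        "multimodal": bool(spread > 1e-3),
    }
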