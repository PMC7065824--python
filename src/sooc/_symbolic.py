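"""Symbolic engine behind every plant.

A plant is declared once as a sympy drift ``f(x, u)`` and diffusion
``G(x, u)``.  From these expressions this module generates fast, vectorized
numeric callables for

* the drift, its state Jacobian ``F = df/dx`` and the diffusion,
* the coupled mean/covariance (moment) right-hand side
  ``d/dt (m, vech P) = (f(m,u), F P + P F' + G G')`` evaluated at the mean,
  together with its exact Jacobian with respect to ``(m, vech P, u)``.

The Jacobians are what make direct transcription of the equivalent
deterministic problem tractable: every defect-constraint derivative is exact
(sympy-differentiated), not finite-differenced.

The covariance is carried as its upper-triangular half ``vech P`` in
row-major order (P11, P12, .., P1n, P22, ..), matching the CSV schema.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np
import sympy as sp

__all__ = [
    "vech_indices",
    "vech",
    "unvech",
    "SymbolicDynamics",
]


def vech_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper triangle in row-major order."""
    rows, cols = np.triu_indices(n)
    return rows, cols


def vech(P: np.ndarray) -> np.ndarray:
    """Upper-triangular half of a symmetric matrix, row-major."""
    P = np.asarray(P)
    n = P.shape[-1]
    r, c = vech_indices(n)
    return P[..., r, c]


def unvech(v: np.ndarray, n: int) -> np.ndarray:
    """Symmetric matrix from its upper-triangular half."""
    v = np.asarray(v)
    r, c = vech_indices(n)
    P = np.zeros(v.shape[:-1] + (n, n), dtype=v.dtype)
    P[..., r, c] = v
    P[..., c, r] = v
    return P


def _lambdify_vec(args, exprs, shape):
    """Lambdify a flat list of expressions into one broadcast-stacked array.

    Constant expressions do not broadcast on their own under
    ``sympy.lambdify``; the wrapper broadcasts every output against the
    input batch shape and stacks along trailing axes of ``shape``.
    """
    fn = sp.lambdify(args, exprs, modules="numpy", cse=True)

    def call(*cols):
        cols = [np.asarray(c, dtype=float) for c in cols]
        batch = np.broadcast_shapes(*(c.shape for c in cols))
        out = fn(*cols)
        stacked = np.stack(
            [np.broadcast_to(np.asarray(o, dtype=float), batch) for o in out],
            axis=-1,
        )
        return stacked.reshape(batch + shape)

    return call


class SymbolicDynamics:
    """Drift/diffusion expressions plus generated numeric callables.

    Parameters
    ----------
    x, u : sequences of sympy symbols (declared real)
    f : sympy Matrix, shape (n, 1) - the drift
    G : sympy Matrix, shape (n, m) - the diffusion
    params : dict, for bookkeeping only (values already substituted)
    """

    def __init__(self, name, x, u, f, G, params=None):
        self.name = name
        self.x = tuple(x)
        self.u = tuple(u)
        self.f_expr = sp.Matrix(f)
        self.G_expr = sp.Matrix(G)
        self.params = dict(params or {})
        self.n = len(self.x)
        self.p = len(self.u)
        if self.f_expr.shape != (self.n, 1):
            raise ValueError(
                f"drift must be {self.n}x1, got {self.f_expr.shape}"
            )
        if self.G_expr.shape[0] != self.n:
            raise ValueError(
                f"diffusion must have {self.n} rows, got {self.G_expr.shape}"
            )
        self.m_noise = self.G_expr.shape[1]
        # moment-space symbols: mean and vech of the covariance
        self.m_syms = sp.symbols(f"_m0:{self.n}", real=True)
        r, c = vech_indices(self.n)
        self.ntri = len(r)
        self.P_syms = sp.symbols(f"_P0:{self.ntri}", real=True)
        P = sp.zeros(self.n, self.n)
        for k, (i, j) in enumerate(zip(r, c)):
            P[int(i), int(j)] = self.P_syms[k]
            P[int(j), int(i)] = self.P_syms[k]
        self.P_matrix = P
        self.nz = self.n + self.ntri

    # -- raw plant callables ------------------------------------------------

    @cached_property
    def F_expr(self):
        return self.f_expr.jacobian(self.x)

    @cached_property
    def _drift(self):
        return _lambdify_vec(
            self.x + self.u, list(self.f_expr), (self.n,)
        )

    @cached_property
    def _drift_jac(self):
        flat = [e for row in self.F_expr.tolist() for e in row]
        return _lambdify_vec(self.x + self.u, flat, (self.n, self.n))

    @cached_property
    def _diffusion(self):
        flat = [e for row in self.G_expr.tolist() for e in row]
        return _lambdify_vec(self.x + self.u, flat, (self.n, self.m_noise))

    def _cols(self, X, U):
        X = np.asarray(X, dtype=float)
        U = np.asarray(U, dtype=float)
        return [X[..., i] for i in range(self.n)] + [
            U[..., i] for i in range(self.p)
        ]

    def drift(self, x, u, t=None):
        return self._drift(*self._cols(x, u))

    def drift_jacobian(self, x, u, t=None):
        return self._drift_jac(*self._cols(x, u))

    def diffusion(self, x, u, t=None):
        return self._diffusion(*self._cols(x, u))

    @property
    def diffusion_state_dependent(self) -> bool:
        return any(
            s in self.G_expr.free_symbols for s in self.x
        )

    # -- moment dynamics ----------------------------------------------------

    @cached_property
    def moment_rhs_expr(self):
        """d/dt (m, vech P) with the mean-evaluated Gaussian closure."""
        sub = dict(zip(self.x, self.m_syms))
        fm = self.f_expr.subs(sub)
        Fm = self.F_expr.subs(sub)
        Gm = self.G_expr.subs(sub)
        P = self.P_matrix
        Pdot = Fm * P + P * Fm.T + Gm * Gm.T
        r, c = vech_indices(self.n)
        entries = [fm[i, 0] for i in range(self.n)]
        entries += [Pdot[int(i), int(j)] for i, j in zip(r, c)]
        return sp.Matrix(entries)

    @cached_property
    def _moment_args(self):
        return tuple(self.m_syms) + tuple(self.P_syms) + tuple(self.u)

    @cached_property
    def _moment_rhs(self):
        return _lambdify_vec(
            self._moment_args, list(self.moment_rhs_expr), (self.nz,)
        )

    @cached_property
    def _moment_jac(self):
        zvars = list(self._moment_args)
        J = self.moment_rhs_expr.jacobian(zvars)
        flat = [e for row in J.tolist() for e in row]
        return _lambdify_vec(
            self._moment_args, flat, (self.nz, self.nz + self.p)
        )

    def _zcols(self, Z, U):
        Z = np.asarray(Z, dtype=float)
        U = np.asarray(U, dtype=float)
        return [Z[..., i] for i in range(self.nz)] + [
            U[..., i] for i in range(self.p)
        ]

    def moment_rhs(self, z, u, t=None):
        """Time derivative of the stacked moment state (m, vech P)."""
        return self._moment_rhs(*self._zcols(z, u))

    def moment_rhs_jac(self, z, u, t=None):
        """Jacobian of :meth:`moment_rhs` w.r.t. (m, vech P, u)."""
        return self._moment_jac(*self._zcols(z, u))
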