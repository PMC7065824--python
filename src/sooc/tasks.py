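"""Noise models and task cost functions.

Each task couples a cost (an effort/variance trade-off, possibly extended
with smoothness or projected-variance terms), boundary conditions on the
moments, and a noise model, into a :class:`TaskSpec` that the transcription
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .moments import ConfigurationError, QuadraticCost

__all__ = [
    "NoiseSpec",
    "TaskSpec",
    "cocontraction_noise",
    "cocontraction_noise_expr",
    "missenard_cost",
    "burdet_cost",
    "hogan_posture_cost",
    "bennett_cost",
]

DEG = np.pi / 180.0


@dataclass(frozen=True)
class NoiseSpec:
    """Descriptor of a noise model.

    kinds:
      additive_accel            g_vec: constant diffusion column
      additive_torque           sigma: per-joint torque noise, mapped
                                through the inverse inertia matrix
      signal_dependent_torque   frac: diffusion = frac * tau / I
      cocontraction_aware       d: d*(|u1-u2|^1.5 + 0.01*|u1+u2|^1.5)
    """

    kind: str
    g_vec: tuple = (0.0, 0.1)
    sigma: tuple = (0.025, 0.025)
    frac: float = 0.2
    d: float = 4.0

    def __post_init__(self):
        if self.kind not in (
            "additive_accel",
            "additive_torque",
            "signal_dependent_torque",
            "cocontraction_aware",
        ):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.d < 0 or self.frac < 0 or any(
            s < 0 for s in self.sigma
        ):
            raise ConfigurationError("noise magnitudes must be >= 0")


def cocontraction_noise_expr(u1, u2, d):
    """Symbolic co-contraction-aware diffusion entry."""
    return d * (
        sp.Abs(u1 - u2) ** sp.Rational(3, 2)
        + 0.01 * sp.Abs(u1 + u2) ** sp.Rational(3, 2)
    )


def cocontraction_noise(u1, u2, d: float = 4.0) -> float:
    """Co-contraction-aware signal-dependent noise magnitude.

    Reciprocal activation (u1 - u2 large) is noisy; balanced co-contraction
    at the same total drive is ~100x quieter, which is what makes stiffening
    worthwhile for accuracy.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    out = d * (
        np.abs(u1 - u2) ** 1.5 + 0.01 * np.abs(u1 + u2) ** 1.5
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class TaskSpec:
    """A task: cost + boundary conditions + duration (+ solver hints)."""

    cost: QuadraticCost
    t_f: float
    m0: np.ndarray
    P0: np.ndarray | None = None          # None with terminal_cov="cyclic"
    terminal_mean: np.ndarray | None = None
    terminal_cov: str = "free"            # "free" | "cyclic"
    terminal_constraints: list = field(default_factory=list)
    control_bounds: tuple | None = None   # overrides the plant's default
    deterministic_states: tuple = ()
    name: str = ""

    def __post_init__(self):
        if self.t_f <= 0:
            raise ConfigurationError("t_f must be > 0")
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.P0 is not None:
            self.P0 = np.asarray(self.P0, dtype=float)
        if self.terminal_mean is not None:
            self.terminal_mean = np.asarray(self.terminal_mean, dtype=float)


# ---------------------------------------------------------------------------
# Task builders
# ---------------------------------------------------------------------------

def missenard_cost(
    q_var: float,
    t_f: float = 0.475,
    amplitude_deg: tuple = (25.0, 65.0),
) -> TaskSpec:
    """Fast elbow reach with terminal-variance penalty.

    Effort integrand u'u; terminal term q_var * (P_theta + 0.1 * P_omega);
    the mean is driven from 25 deg to 65 deg (hard terminal constraint,
    zero initial covariance).
    """
    if q_var < 0:
        raise ConfigurationError("q_var must be >= 0")
    Qf = q_var * np.diag([1.0, 0.1])
    cost = QuadraticCost(R=np.eye(2), Q=None, Qf=None, Qf_cov=Qf)
    return TaskSpec(
        cost=cost,
        t_f=t_f,
        m0=np.array([amplitude_deg[0] * DEG, 0.0]),
        P0=np.zeros((2, 2)),
        terminal_mean=np.array([amplitude_deg[1] * DEG, 0.0]),
        terminal_cov="free",
        name=f"missenard_qvar{q_var:g}_tf{t_f:g}",
    )


def hogan_posture_cost(t_f: float = 5.0) -> TaskSpec:
    """Hold the unstable upright forearm posture: R = I, Q = Qf =
    diag(1e4, 1e3), final mean pinned at zero, final covariance free."""
    cost = QuadraticCost(
        R=np.eye(2),
        Q=np.diag([1e4, 1e3]),
        Qf=np.diag([1e4, 1e3]),
    )
    return TaskSpec(
        cost=cost,
        t_f=t_f,
        m0=np.zeros(2),
        P0=np.zeros((2, 2)),
        terminal_mean=np.zeros(2),
        terminal_cov="free",
        name="hogan_posture",
    )


def bennett_cost(
    plant,
    q_var: float = 1e4,
    alpha: float = 1.0,
    q_v: float = 0.01,
    t_f: float = 0.75,
    amplitude: float = 1.0,
) -> TaskSpec:
    """Cyclic single-joint reach for the joint-level plant: effort
    tau^2 + alpha*kappa^2 plus running and terminal deviation-variance
    q_var*(E[Delta^2] + q_v*E[dDelta^2]); equal initial and final
    covariance (cyclical movement)."""
    dyn = plant.dynamics
    if dyn.n != 4 or dyn.p != 2:
        raise ConfigurationError("bennett_cost needs the joint-level plant")
    R = np.diag([1.0, alpha])
    Q = np.zeros((4, 4))
    Q[2, 2] = q_var
    Q[3, 3] = q_var * q_v
    cost = QuadraticCost(R=R, Q=Q, Qf=Q.copy())
    return TaskSpec(
        cost=cost,
        t_f=t_f,
        m0=np.array([0.0, 0.0, 0.0, 0.0]),
        P0=None,
        terminal_mean=np.array([amplitude, 0.0, 0.0, 0.0]),
        terminal_cov="cyclic",
        # the reference subsystem is deterministic: its covariance rows are
        # structurally zero and are pinned, not optimized
        deterministic_states=(0, 1),
        name=f"bennett_tf{t_f:g}",
    )


def _cartesian_accel_sq(plant):
    """|(xdd, ydd)|^2 of the mean endpoint, as a symbolic function of
    (m, u): differentiate the forward kinematics twice through the drift."""
    from .plants import _fk_exprs

    params = plant.meta.get("arm_params")
    if params is None:
        raise ConfigurationError(
            "smoothness term requires the two-joint arm plant"
        )
    dyn = plant.dynamics
    q1, q2, w1, w2 = dyn.x
    fk = _fk_exprs(params, q1, q2)
    J = fk.jacobian([q1, q2])
    # xdd = J qdd + dJ/dt qdot, with qdd taken from the drift
    qdd = sp.Matrix([dyn.f_expr[2], dyn.f_expr[3]])
    Jdot = sp.zeros(2, 2)
    for a, qa in ((q1, w1), (q2, w2)):
        Jdot += J.diff(a) * qa
    acc = J * qdd + Jdot * sp.Matrix([w1, w2])
    expr = acc[0] ** 2 + acc[1] ** 2
    sub = dict(zip(dyn.x, dyn.m_syms))
    return expr.subs(sub)


def _task_space_cov(plant, normal=None):
    """q_var-free part of Phi: trace(J P_q J') or n' J P_q J' n at the
    final mean posture (P_q = joint-position block of P)."""
    from .plants import _fk_exprs

    params = plant.meta["arm_params"]
    dyn = plant.dynamics
    mq = dyn.m_syms[:2]
    fk = _fk_exprs(params, *mq)
    J = fk.jacobian(mq)
    Pq = dyn.P_matrix[:2, :2]
    S = J * Pq * J.T
    if normal is None:
        return sp.trace(S)
    nvec = sp.Matrix([float(normal[0]), float(normal[1])])
    return (nvec.T * S * nvec)[0, 0]


def burdet_cost(
    plant,
    q_var: float,
    t_f: float = 0.75,
    smoothness_on: bool = True,
    start_xy: tuple = (0.0, 0.30),
    target_xy: tuple = (0.0, 0.55),
    line_normal: tuple | None = None,
) -> TaskSpec:
    """Two-joint reach cost: running u'u + 1/2 |mean Cartesian accel|^2,
    terminal q_var * projected task-space positional covariance.

    With ``line_normal`` the terminal variance is penalized only orthogonal
    to a target line through ``target_xy`` and the terminal mean is
    constrained onto that line (point-to-line task); otherwise the full
    positional covariance trace is penalized and the mean is pinned at
    ``target_xy``.
    """
    from .plants import _fk_exprs, inverse_kinematics

    if q_var < 0:
        raise ConfigurationError("q_var must be >= 0")
    dyn = plant.dynamics
    if dyn.n != 4:
        raise ConfigurationError(
            "smoothness/task-space terms need the two-joint arm plant"
        )
    params = plant.meta["arm_params"]
    extra_run = (
        sp.Rational(1, 2) * _cartesian_accel_sq(plant)
        if smoothness_on
        else None
    )
    extra_term = (
        q_var * _task_space_cov(plant, line_normal) if q_var > 0 else None
    )

    q0 = inverse_kinematics(params, start_xy)
    m0 = np.array([q0[0], q0[1], 0.0, 0.0])
    terminal_constraints = []
    if line_normal is None:
        qf = inverse_kinematics(params, target_xy)
        terminal_mean = np.array([qf[0], qf[1], 0.0, 0.0])
    else:
        # mean endpoint on the line, zero mean velocity
        terminal_mean = None
        mq = dyn.m_syms
        fk = _fk_exprs(params, mq[0], mq[1])
        n1, n2 = float(line_normal[0]), float(line_normal[1])
        on_line = n1 * (fk[0] - float(target_xy[0])) + n2 * (
            fk[1] - float(target_xy[1])
        )
        terminal_constraints = [on_line, mq[2], mq[3]]
    cost = QuadraticCost(
        R=np.eye(6),
        Q=None,
        Qf=None,
        extra_running=extra_run,
        extra_terminal=extra_term,
    )
    return TaskSpec(
        cost=cost,
        t_f=t_f,
        m0=m0,
        P0=np.zeros((4, 4)),
        terminal_mean=terminal_mean,
        terminal_cov="free",
        terminal_constraints=terminal_constraints,
        name=f"burdet_qvar{q_var:g}",
    )
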