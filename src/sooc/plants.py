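"""Musculoskeletal plants: an inverted-pendulum forearm with antagonist
muscles, a joint-level torque/stiffness model, and one- and two-joint
Katayama-Kawato muscle models.

Conventions
-----------
* All internal angles are radians; user-facing reports are in degrees.
* Joint stiffness is K = -d(tau_actuator)/dq, so positive K is restoring
  (stabilizing).  For the pendulum this is the muscular stiffness
  K*(u1+u2), to be compared against the destabilizing gravitational level
  m*g*l_c.
* The two-joint model's per-muscle constants are NOT printed in the source
  material for the one-joint model; the defaults shipped here are a
  clearly-labelled surrogate set (standard anthropometric two-link values,
  one-joint-style muscle coefficients, rest lengths anchored at a reference
  posture).  Only qualitative/ordering behavior is claimed for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from ._symbolic import SymbolicDynamics
from .moments import BilinearSystem, NonlinearPlant, ConfigurationError

__all__ = [
    "PendulumParams",
    "JointImpedanceParams",
    "MuscleParams1Dof",
    "ArmParams2Dof",
    "DivergentField",
    "hogan_pendulum",
    "joint_impedance_plant",
    "kk_onejoint",
    "kk_twojoint",
    "joint_stiffness",
    "endpoint_maps",
    "endpoint_stiffness",
    "inverse_kinematics",
]


def _positive(**kwargs):
    for name, value in kwargs.items():
        if value <= 0:
            raise ConfigurationError(f"{name} must be > 0, got {value}")


# ---------------------------------------------------------------------------
# Hogan inverted-pendulum forearm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PendulumParams:
    """Forearm-as-inverted-pendulum, actuated by an antagonist muscle pair.

    theta = 0 is the upright (unstable) orientation.  A hand-held load
    shifts the inertia by m_load*l**2 and the gravitational torque
    coefficient by m_load*g*l.
    """

    I: float = 0.0588      # kg m^2
    m: float = 1.44        # kg
    l_c: float = 0.21      # m, center of mass
    l: float = 0.35        # m, segment length
    b: float = 1.0         # N m s / rad
    g: float = 9.81        # m / s^2
    T: float = 1.0         # N m per unit (u1 - u2)
    K: float = 1.0         # N m / rad per unit (u1 + u2)
    m_load: float = 0.0    # kg, optional load at the hand

    def __post_init__(self):
        _positive(I=self.I, m=self.m, l_c=self.l_c, l=self.l)
        if self.m_load < 0:
            raise ConfigurationError("m_load must be >= 0")

    @property
    def inertia(self) -> float:
        return self.I + self.m_load * self.l**2

    @property
    def gravity_torque_coeff(self) -> float:
        """Coefficient of sin(theta): m*g*l_c (+ m_load*g*l when loaded)."""
        return self.m * self.g * self.l_c + self.m_load * self.g * self.l


def hogan_pendulum(
    params: PendulumParams = PendulumParams(),
    linearized: bool = True,
    noise=(0.0, 0.1),
):
    """The antagonist-pair pendulum, either as the small-angle bilinear
    system or as the full sin(theta) nonlinear plant.

    ``noise`` is the constant acceleration-level diffusion column G (a
    2-vector or an ``additive_accel`` NoiseSpec).
    """
    from .tasks import NoiseSpec

    if isinstance(noise, NoiseSpec):
        if noise.kind != "additive_accel":
            raise ConfigurationError(
                f"pendulum supports additive_accel noise, got {noise.kind}"
            )
        noise = noise.g_vec
    Ie = params.inertia
    mgl = params.gravity_torque_coeff
    Gcol = np.asarray(noise, dtype=float).reshape(2, 1)

    if linearized:
        A = np.array([[0.0, 1.0], [mgl / Ie, -params.b / Ie]])
        B = np.array([[0.0, 0.0], [params.T / Ie, -params.T / Ie]])
        Ni = np.array([[0.0, 0.0], [-params.K / Ie, 0.0]])
        sys = BilinearSystem(A, B, [Ni, Ni], Gcol, name="hogan_bilinear")
        dyn = sys.dynamics
        x, u = dyn.x, dyn.u
        tau = (
            params.T * (u[0] - u[1])
            - params.K * (u[0] + u[1]) * x[0]
            - params.b * x[1]
        )
        sys.meta = {"params": params}
        _attach_stiffness(sys, sp.Matrix([tau]), [x[0]], dyn)
        return sys

    th, om = sp.symbols("theta omega", real=True)
    u1, u2 = sp.symbols("u1 u2", real=True, nonnegative=True)
    tau = params.T * (u1 - u2) - params.K * (u1 + u2) * th - params.b * om
    f = sp.Matrix([om, (tau + mgl * sp.sin(th)) / Ie])
    G = sp.Matrix([[float(Gcol[0, 0])], [float(Gcol[1, 0])]])
    dyn = SymbolicDynamics("hogan_pendulum", (th, om), (u1, u2), f, G)
    plant = NonlinearPlant(
        dynamics=dyn,
        parameters=vars_dict(params),
        control_bounds=(np.array([0.0, 0.0]), np.array([np.inf, np.inf])),
        state_names=("theta", "omega"),
        torque_expr=sp.Matrix([tau]),
    )
    _attach_stiffness(plant, sp.Matrix([tau]), [th], dyn)
    return plant


def vars_dict(params) -> dict:
    return {k: getattr(params, k) for k in params.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Joint-level torque/stiffness model (reference trajectory + deviations)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointImpedanceParams:
    """Joint-level plant with explicit force (tau) and impedance (kappa)
    controls.

    The state is (Theta, dTheta, Delta, dDelta): a reference trajectory
    obeying the rigid-body dynamics and the stochastic deviation from it.
    kappa >= 0 sets the joint stiffness K_s*kappa; the co-modulated damping
    is 2*zeta*sqrt(I*K_s*kappa), i.e. a constant damping ratio zeta of the
    deviation subsystem for every kappa.
    """

    I: float = 0.072      # kg m^2
    b: float = 0.0        # N m s / rad
    K_s: float = 1.0      # stiffness per unit kappa (kappa in N m / rad)
    zeta: float = 0.5     # target damping ratio of the Delta subsystem
    gravity_on: bool = False
    m: float = 1.44       # used only when gravity_on
    l_c: float = 0.21
    g: float = 9.81
    torque_noise_frac: float = 0.2  # diffusion = frac * tau / I on dDelta

    def __post_init__(self):
        _positive(I=self.I, K_s=self.K_s)
        if self.zeta < 0:
            raise ConfigurationError("zeta must be >= 0")


def joint_impedance_plant(
    params: JointImpedanceParams = JointImpedanceParams(),
) -> NonlinearPlant:
    Th, dTh, De, dDe = sp.symbols("Theta dTheta Delta dDelta", real=True)
    tau, kap = sp.symbols("tau kappa", real=True)
    I, b, Ks, zeta = params.I, params.b, params.K_s, params.zeta
    damp = 2 * zeta * sp.sqrt(I * Ks * kap)
    if params.gravity_on:
        grav = params.m * params.g * params.l_c
        ddTh = (tau - b * dTh + grav * sp.sin(Th)) / I
        ddDe = (
            -Ks * kap * De - damp * dDe - b * dDe
            + grav * (sp.sin(De + Th) - sp.sin(Th))
        ) / I
    else:
        ddTh = (tau - b * dTh) / I
        ddDe = (-Ks * kap * De - damp * dDe - b * dDe) / I
    f = sp.Matrix([dTh, ddTh, dDe, ddDe])
    G = sp.Matrix([0, 0, 0, params.torque_noise_frac * tau / I])
    dyn = SymbolicDynamics(
        "joint_impedance", (Th, dTh, De, dDe), (tau, kap), f, G
    )
    lb = np.array([-np.inf, 1e-7])  # kappa > 0 (sqrt gradient finite)
    ub = np.array([np.inf, np.inf])
    plant = NonlinearPlant(
        dynamics=dyn,
        parameters=vars_dict(params),
        control_bounds=(lb, ub),
        state_names=("Theta", "dTheta", "Delta", "dDelta"),
        torque_expr=sp.Matrix([-Ks * kap * De - (damp + b) * dDe]),
    )
    _attach_stiffness(plant, plant.torque_expr, [De], dyn)
    return plant


# ---------------------------------------------------------------------------
# One-joint Katayama-Kawato muscle model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuscleParams1Dof:
    """Single-joint arm driven by a flexor/extensor muscle pair whose
    activation modulates both torque and intrinsic viscoelasticity.

    Muscle torque: tau_i = -a_i T_i with tension
    T_i = (k0 + k u_i)(r_i u_i + (l0 - lm_i) + a_i theta)
          + (b0 + b u_i) a_i dtheta.
    """

    I: float = 0.0588          # kg m^2
    k: float = 1621.6          # N/m activation stiffness gain
    k0: float = 810.8          # N/m intrinsic stiffness
    b: float = 108.1           # N s/m activation viscosity gain
    b0: float = 54.1           # N s/m intrinsic viscosity
    a: tuple = (0.025, 0.025)  # m moment arms (flexor, extensor)
    r: tuple = (-0.02182, 0.02182)   # m activation rest-length gains
    rest_offset: tuple = (-0.0567, -0.00436)  # m, l0 - lm_i

    def __post_init__(self):
        _positive(I=self.I, k=self.k, k0=self.k0, b=self.b, b0=self.b0)


def _muscle_tension(params, ui, ri, ei, ai, th, om):
    return (params.k0 + params.k * ui) * (ri * ui + ei + ai * th) + (
        params.b0 + params.b * ui
    ) * ai * om


def kk_onejoint(
    params: MuscleParams1Dof = MuscleParams1Dof(),
    noise_d=4.0,
    noise_expr=None,
) -> NonlinearPlant:
    """One-joint two-muscle plant with co-contraction-aware
    signal-dependent noise of overall magnitude ``noise_d`` (a float or a
    ``cocontraction_aware`` NoiseSpec; the diffusion is
    d*(|u1-u2|^1.5 + 0.01*|u1+u2|^1.5) at acceleration level).
    """
    from .tasks import NoiseSpec

    if isinstance(noise_d, NoiseSpec):
        if noise_d.kind != "cocontraction_aware":
            raise ConfigurationError(
                "kk_onejoint expects cocontraction_aware noise, got "
                f"{noise_d.kind}"
            )
        noise_d = noise_d.d
    th, om = sp.symbols("theta omega", real=True)
    u1, u2 = sp.symbols("u1 u2", real=True, nonnegative=True)
    taus = [
        -params.a[i]
        * _muscle_tension(
            params, u, params.r[i], params.rest_offset[i], params.a[i], th, om
        )
        for i, u in enumerate((u1, u2))
    ]
    f = sp.Matrix([om, (taus[0] + taus[1]) / params.I])
    if noise_expr is None:
        from .tasks import cocontraction_noise_expr

        noise_expr = cocontraction_noise_expr(u1, u2, noise_d)
    G = sp.Matrix([0, noise_expr])
    dyn = SymbolicDynamics("kk_onejoint", (th, om), (u1, u2), f, G)
    plant = NonlinearPlant(
        dynamics=dyn,
        parameters=vars_dict(params),
        control_bounds=(np.zeros(2), np.array([np.inf, np.inf])),
        state_names=("theta", "omega"),
        torque_expr=sp.Matrix([taus[0] + taus[1]]),
    )
    _attach_stiffness(plant, plant.torque_expr, [th], dyn)
    return plant


# ---------------------------------------------------------------------------
# Two-joint six-muscle arm (surrogate parameters)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmParams2Dof:
    """Planar two-link arm with six muscles (4 mono-, 2 bi-articular).

    SURROGATE parameter set: the published six-muscle constants live in an
    external reference; these defaults are standard anthropometric two-link
    values with one-joint-style muscle coefficients, shipped so that all
    property tests run self-contained.  Moment arms are constant; muscle
    lengths are affine in the joint angles; rest lengths are anchored so
    that passive muscle stretch vanishes at ``q_ref``.
    """

    L: tuple = (0.30, 0.33)          # m link lengths
    mass: tuple = (1.93, 1.52)       # kg
    com: tuple = (0.165, 0.19)       # m, proximal-to-COM distance
    inertia: tuple = (0.0141, 0.0188)  # kg m^2 about COM
    # columns: sh-flex, sh-ext, el-flex, el-ext, bi-flex, bi-ext
    moment_arms: tuple = (
        (0.040, -0.040, 0.0, 0.0, 0.028, -0.028),
        (0.0, 0.0, 0.025, -0.025, 0.035, -0.035),
    )
    k: float = 1621.6
    k0: float = 810.8
    b: float = 108.1
    b0: float = 54.1
    r: float = -0.02182             # activation rest-length gain (all)
    q_ref: tuple = (1.3181160716528182, 1.9321157109101684)
    # ^ inverse kinematics of the mid-reach hand position (0, 0.425) m

    def __post_init__(self):
        _positive(
            L1=self.L[0], L2=self.L[1], m1=self.mass[0], m2=self.mass[1]
        )


@dataclass(frozen=True)
class DivergentField:
    """Horizontal endpoint force F = beta * x, destabilizing lateral
    deviations from the straight-ahead path (x = 0)."""

    beta: float = 40.0  # N/m


def _fk_exprs(params: ArmParams2Dof, q1, q2):
    L1, L2 = params.L
    x = L1 * sp.cos(q1) + L2 * sp.cos(q1 + q2)
    y = L1 * sp.sin(q1) + L2 * sp.sin(q1 + q2)
    return sp.Matrix([x, y])


def kk_twojoint(
    params: ArmParams2Dof = ArmParams2Dof(),
    field: DivergentField | None = None,
    sigma=(0.025, 0.025),
) -> NonlinearPlant:
    """Two-joint six-muscle plant; additive torque noise (a sigma pair or
    an ``additive_torque`` NoiseSpec) mapped through the inverse inertia
    matrix (state-dependent diffusion, closed at the mean), optionally
    inside a divergent force field."""
    from .tasks import NoiseSpec

    if isinstance(sigma, NoiseSpec):
        if sigma.kind != "additive_torque":
            raise ConfigurationError(
                f"kk_twojoint expects additive_torque noise, got {sigma.kind}"
            )
        sigma = sigma.sigma
    q1, q2, w1, w2 = sp.symbols("q1 q2 w1 w2", real=True)
    us = sp.symbols("v0:6", real=True, nonnegative=True)
    L1, L2 = params.L
    m1, m2 = params.mass
    s1, s2 = params.com
    I1, I2 = params.inertia

    c2 = sp.cos(q2)
    a11 = I1 + I2 + m1 * s1**2 + m2 * (L1**2 + s2**2 + 2 * L1 * s2 * c2)
    a12 = I2 + m2 * (s2**2 + L1 * s2 * c2)
    a22 = I2 + m2 * s2**2
    M = sp.Matrix([[a11, a12], [a12, a22]])
    h = m2 * L1 * s2 * sp.sin(q2)
    C = sp.Matrix([[-h * w2, -h * (w1 + w2)], [h * w1, 0]])

    A = sp.Matrix(params.moment_arms)  # 2 x 6
    qv = sp.Matrix([q1, q2])
    wv = sp.Matrix([w1, w2])
    qref = sp.Matrix(params.q_ref)
    tau = sp.zeros(2, 1)
    for i in range(6):
        ai = A[:, i]
        stretch = params.r * us[i] + (ai.T * (qv - qref))[0, 0]
        Ti = (params.k0 + params.k * us[i]) * stretch + (
            params.b0 + params.b * us[i]
        ) * (ai.T * wv)[0, 0]
        tau -= ai * Ti

    tau_ext = sp.zeros(2, 1)
    if field is not None:
        fk = _fk_exprs(params, q1, q2)
        J = fk.jacobian([q1, q2])
        tau_ext = J.T * sp.Matrix([field.beta * fk[0], 0])

    Minv = M.inv()
    qdd = Minv * (tau + tau_ext - C * wv)
    f = sp.Matrix([w1, w2, qdd[0], qdd[1]])
    Gtop = sp.zeros(2, 2)
    Gbot = Minv * sp.diag(float(sigma[0]), float(sigma[1]))
    G = sp.Matrix(sp.BlockMatrix([[Gtop], [Gbot]]))
    dyn = SymbolicDynamics(
        "kk_twojoint", (q1, q2, w1, w2), us, f, G
    )
    plant = NonlinearPlant(
        dynamics=dyn,
        parameters={**vars_dict(params), "sigma": tuple(sigma),
                    "beta": 0.0 if field is None else field.beta},
        control_bounds=(np.zeros(6), np.full(6, np.inf)),
        state_names=("q1", "q2", "w1", "w2"),
        torque_expr=tau,
        meta={"arm_params": params},
    )
    _attach_stiffness(plant, tau, [q1, q2], dyn)
    return plant


# ---------------------------------------------------------------------------
# Stiffness and endpoint maps
# ---------------------------------------------------------------------------

def _attach_stiffness(plant, tau_expr, q_syms, dyn):
    Kexpr = -tau_expr.jacobian(q_syms)
    args = dyn.x + dyn.u
    nq = len(q_syms)
    fn = sp.lambdify(args, [e for row in Kexpr.tolist() for e in row],
                     modules="numpy")
    meta = plant.meta if hasattr(plant, "meta") else {}

    def K_of(x, u):
        vals = list(np.asarray(x, dtype=float)) + list(
            np.asarray(u, dtype=float)
        )
        out = np.asarray(fn(*vals), dtype=float).reshape(nq, nq)
        return out

    meta["stiffness_fn"] = K_of
    meta["n_joints"] = nq
    plant.meta = meta


def joint_stiffness(plant, x, u) -> np.ndarray:
    """Joint-space stiffness K = -d(tau_actuator)/dq at (x, u); positive is
    restoring."""
    try:
        fn = plant.meta["stiffness_fn"]
    except (AttributeError, KeyError, TypeError):
        raise ConfigurationError(
            f"plant {getattr(plant, 'name', plant)!r} exposes no torque map"
        )
    return fn(x, u)


def forward_kinematics(params: ArmParams2Dof, q) -> np.ndarray:
    q1, q2 = q
    L1, L2 = params.L
    return np.array(
        [
            L1 * np.cos(q1) + L2 * np.cos(q1 + q2),
            L1 * np.sin(q1) + L2 * np.sin(q1 + q2),
        ]
    )


def arm_jacobian(params: ArmParams2Dof, q) -> np.ndarray:
    q1, q2 = q
    L1, L2 = params.L
    s1, s12 = np.sin(q1), np.sin(q1 + q2)
    c1, c12 = np.cos(q1), np.cos(q1 + q2)
    return np.array(
        [[-L1 * s1 - L2 * s12, -L2 * s12], [L1 * c1 + L2 * c12, L2 * c12]]
    )


def endpoint_stiffness(K: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Cartesian stiffness S = J^-T K J^-1 (congruence transform)."""
    Jinv = np.linalg.inv(J)
    return Jinv.T @ K @ Jinv


def endpoint_maps(params: ArmParams2Dof, q, K: np.ndarray | None = None):
    """Forward kinematics, Jacobian, and (optionally) the endpoint
    stiffness of a supplied joint stiffness matrix."""
    J = arm_jacobian(params, q)
    if abs(np.linalg.det(J)) < 1e-10:
        raise ConfigurationError(
            f"singular arm Jacobian at q = {np.asarray(q)!r}"
        )
    pos = forward_kinematics(params, q)
    if K is None:
        return pos, J, None
    return pos, J, endpoint_stiffness(np.asarray(K, dtype=float), J)


def inverse_kinematics(params: ArmParams2Dof, xy) -> np.ndarray:
    """Elbow-flexed (q2 > 0) inverse kinematics of a hand position."""
    x, y = xy
    L1, L2 = params.L
    d2 = x * x + y * y
    c2 = (d2 - L1 * L1 - L2 * L2) / (2 * L1 * L2)
    if not -1.0 < c2 < 1.0:
        raise ConfigurationError(f"hand position {xy!r} out of workspace")
    q2 = np.arccos(c2)
    q1 = np.arctan2(y, x) - np.arctan2(L2 * np.sin(q2), L1 + L2 * np.cos(q2))
    return np.array([q1, q2])
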