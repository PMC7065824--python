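"""Plant construction: printed parameter values, analytic Jacobians vs
finite differences, stiffness maps, structural properties of the two-link
arm, and the joint-level decoupling."""

import numpy as np
import pytest

import sooc
from sooc.moments import ConfigurationError
from sooc.plants import (
    ArmParams2Dof,
    DivergentField,
    JointImpedanceParams,
    MuscleParams1Dof,
    PendulumParams,
    arm_jacobian,
    endpoint_maps,
    endpoint_stiffness,
    forward_kinematics,
    hogan_pendulum,
    inverse_kinematics,
    joint_impedance_plant,
    joint_stiffness,
    kk_onejoint,
    kk_twojoint,
)

RNG = np.random.default_rng(42)


def _fd_jacobian(f, x, eps=1e-6):
    n = len(x)
    fx = f(x)
    J = np.zeros((len(fx), n))
    for i in range(n):
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        J[:, i] = (f(xp) - f(xm)) / (2 * eps)
    return J


def _plants_for_jacobian_check():
    return [
        ("pendulum", hogan_pendulum(linearized=False), 0.5, 1.0),
        ("impedance", joint_impedance_plant(), 0.5, 5.0),
        ("kk1", kk_onejoint(), 0.5, 0.8),
        ("kk2", kk_twojoint(field=DivergentField(40.0)), 0.3, 0.5),
    ]


@pytest.mark.parametrize(
    "name,plant,xscale,uscale",
    _plants_for_jacobian_check(),
    ids=lambda v: v if isinstance(v, str) else "",
)
def test_drift_jacobian_matches_finite_differences(name, plant, xscale,
                                                   uscale):
    dyn = plant.dynamics
    for _ in range(25):
        x = xscale * RNG.standard_normal(dyn.n)
        if name == "kk2":
            x[:2] = [1.3, 1.9] + 0.3 * RNG.standard_normal(2)
        u = uscale * RNG.random(dyn.p) + 0.05
        J = dyn.drift_jacobian(x, u)
        Jfd = _fd_jacobian(lambda xx: dyn.drift(xx, u), x)
        assert np.allclose(J, Jfd, rtol=1e-5, atol=1e-5), name


def test_hogan_bilinear_matrices_from_printed_parameters():
    p = PendulumParams()
    sys = hogan_pendulum(p, linearized=True)
    assert sys.A[1, 0] == pytest.approx(1.44 * 9.81 * 0.21 / 0.0588)
    assert sys.A[1, 1] == pytest.approx(-1.0 / 0.0588)
    assert np.allclose(sys.B[1], [1 / 0.0588, -1 / 0.0588])
    assert sys.N[0][1, 0] == pytest.approx(-1.0 / 0.0588)

    nog = hogan_pendulum(PendulumParams(g=1e-12), linearized=True)
    assert abs(nog.A[1, 0]) < 1e-9


def test_hogan_loading_rule():
    """A hand-held load raises the inertia by m_load*l^2 and the gravity
    torque coefficient by m_load*g*l."""
    loaded = PendulumParams(m_load=2.268)
    assert loaded.inertia == pytest.approx(0.0588 + 2.268 * 0.35**2)
    assert loaded.gravity_torque_coeff == pytest.approx(
        1.44 * 9.81 * 0.21 + 2.268 * 9.81 * 0.35
    )
    sys = hogan_pendulum(loaded, linearized=True)
    assert sys.A[1, 0] == pytest.approx(
        loaded.gravity_torque_coeff / loaded.inertia
    )


def test_small_angle_linearization_of_gravity():
    """The state Jacobian of the sin(theta) plant at theta = 0 equals the
    bilinear drift matrix: linearization amounts to linearizing the
    gravitational torque."""
    p = PendulumParams()
    nonlin = hogan_pendulum(p, linearized=False)
    bilin = hogan_pendulum(p, linearized=True)
    u = np.array([0.7, 0.4])
    F = nonlin.drift_jacobian(np.zeros(2), u)
    Ab = bilin.A + sum(Ni * ui for Ni, ui in zip(bilin.N, u))
    assert np.allclose(F, Ab, atol=1e-12)


def test_kk_onejoint_printed_parameters_roundtrip():
    p = MuscleParams1Dof()
    assert (p.I, p.k, p.k0, p.b, p.b0) == (0.0588, 1621.6, 810.8, 108.1,
                                           54.1)
    assert p.a == (0.025, 0.025)
    assert p.r == (-0.02182, 0.02182)
    assert p.rest_offset == (-0.0567, -0.00436)


def test_kk_onejoint_passive_stiffness_and_monotonicity(kk1_plant):
    p = MuscleParams1Dof()
    K0 = joint_stiffness(kk1_plant, np.array([0.3, 0.0]), np.zeros(2))
    assert K0[0, 0] == pytest.approx(p.k0 * (p.a[0] ** 2 + p.a[1] ** 2),
                                     rel=1e-12)
    levels = [
        joint_stiffness(kk1_plant, np.array([0.3, 0.0]), np.array([u, u]))[
            0, 0
        ]
        for u in np.linspace(0, 1, 6)
    ]
    assert np.all(np.diff(levels) > 0)


def test_kk_onejoint_passive_torque_formula(kk1_plant):
    """At zero activation and velocity the net torque is the sum of the
    two passive elastic terms."""
    p = MuscleParams1Dof()
    th = 0.7
    expected = -p.a[0] * p.k0 * (p.rest_offset[0] + p.a[0] * th) - p.a[
        1
    ] * p.k0 * (p.rest_offset[1] + p.a[1] * th)
    f = kk1_plant.drift(np.array([th, 0.0]), np.zeros(2))
    assert f[1] == pytest.approx(expected / p.I, rel=1e-10)


def test_joint_impedance_decoupling_structure():
    """Gravity off: the reference and deviation subsystems do not talk to
    each other (cross-blocks of the state Jacobian vanish), and kappa/tau
    only drive their own subsystems."""
    plant = joint_impedance_plant(JointImpedanceParams(gravity_on=False))
    dyn = plant.dynamics
    for _ in range(10):
        x = RNG.standard_normal(4)
        u = np.array([RNG.standard_normal(), 2.0 + RNG.random()])
        F = dyn.drift_jacobian(x, u)
        assert np.allclose(F[:2, 2:], 0.0, atol=1e-12)
        assert np.allclose(F[2:, :2], 0.0, atol=1e-12)


def test_joint_impedance_damping_ratio():
    """With constant kappa and no extra damping, the deviation subsystem
    has damping ratio zeta for every kappa."""
    params = JointImpedanceParams(I=0.072, b=0.0, zeta=0.5)
    plant = joint_impedance_plant(params)
    for kappa in [0.5, 2.0, 10.0]:
        F = plant.dynamics.drift_jacobian(
            np.zeros(4), np.array([0.0, kappa])
        )
        # char poly of Delta block: s^2 + c/I s + Ks*kappa/I
        wn = np.sqrt(params.K_s * kappa / params.I)
        zeta = -F[3, 3] / (2 * wn)
        assert zeta == pytest.approx(params.zeta, rel=1e-10)
    K = joint_stiffness(plant, np.zeros(4), np.array([0.0, 3.7]))
    assert K[0, 0] == pytest.approx(params.K_s * 3.7, rel=1e-12)


def test_two_joint_inertia_spd_and_coriolis_structure(arm_plant):
    params = ArmParams2Dof()
    dyn = arm_plant.dynamics
    for q2 in np.linspace(0.3, 2.5, 7):
        for q1 in np.linspace(0.2, 2.2, 5):
            x = np.array([q1, q2, 0.0, 0.0])
            # with qdot = 0, Coriolis contributes nothing: acceleration is
            # M^-1 tau, and M must be SPD (checked via the noise block,
            # G_bottom = M^-1 diag(sigma))
            G = dyn.diffusion(x, np.zeros(6))
            Minv = G[2:] @ np.diag(1.0 / np.array(params.mass) * 0)  # unused
            f = dyn.drift(x, np.zeros(6))
            assert np.all(np.isfinite(f))
    # skew-symmetry of Mdot - 2C for the standard Christoffel form
    import sympy as sp

    q1s, q2s, w1s, w2s = dyn.x
    m2, L1, s2 = params.mass[1], params.L[0], params.com[1]
    h = m2 * L1 * s2 * sp.sin(q2s)
    C = sp.Matrix([[-h * w2s, -h * (w1s + w2s)], [h * w1s, 0]])
    M = sp.zeros(2, 2)
    c2 = sp.cos(q2s)
    M[0, 0] = (params.inertia[0] + params.inertia[1] + params.mass[0]
               * params.com[0] ** 2
               + m2 * (L1**2 + s2**2 + 2 * L1 * s2 * c2))
    M[0, 1] = M[1, 0] = params.inertia[1] + m2 * (s2**2 + L1 * s2 * c2)
    M[1, 1] = params.inertia[1] + m2 * s2**2
    Mdot = M.diff(q2s) * w2s
    S = sp.simplify(Mdot - 2 * C)
    assert sp.simplify(S + S.T) == sp.zeros(2, 2)


def test_divergent_field_contribution(arm_plant):
    """The field adds M^-1 J^T (beta x, 0): zero on the midline, linear in
    the lateral hand coordinate."""
    params = ArmParams2Dof()
    free = arm_plant
    field = kk_twojoint(params, field=DivergentField(beta=40.0))
    u = np.full(6, 0.2)
    q_mid = inverse_kinematics(params, (0.0, 0.45))
    x_mid = np.concatenate([q_mid, [0.0, 0.0]])
    assert np.allclose(
        field.drift(x_mid, u), free.drift(x_mid, u), atol=1e-10
    )
    for lateral in (0.05, 0.10):
        q = inverse_kinematics(params, (lateral, 0.45))
        x = np.concatenate([q, [0.0, 0.0]])
        diff = field.drift(x, u) - free.drift(x, u)
        J = arm_jacobian(params, q)
        M_inv_JT_F = np.linalg.solve(
            _inertia(params, q), J.T @ np.array([40.0 * lateral, 0.0])
        )
        assert np.allclose(diff[2:], M_inv_JT_F, rtol=1e-8, atol=1e-10)
        assert np.allclose(diff[:2], 0.0)


def _inertia(params, q):
    m1, m2 = params.mass
    L1, _ = params.L
    s1, s2 = params.com
    I1, I2 = params.inertia
    c2 = np.cos(q[1])
    a11 = I1 + I2 + m1 * s1**2 + m2 * (L1**2 + s2**2 + 2 * L1 * s2 * c2)
    a12 = I2 + m2 * (s2**2 + L1 * s2 * c2)
    return np.array([[a11, a12], [a12, I2 + m2 * s2**2]])


def test_endpoint_maps_and_congruence():
    params = ArmParams2Dof()
    q = inverse_kinematics(params, (0.05, 0.42))
    assert np.allclose(forward_kinematics(params, q), (0.05, 0.42))
    pos, J, S = endpoint_maps(params, q, K=np.diag([8.0, 5.0]))
    assert np.allclose(S, S.T)
    # pulling S back through J recovers K
    assert np.allclose(J.T @ S @ J, np.diag([8.0, 5.0]), atol=1e-8)
    # identity-Jacobian fixture: S = K
    K = np.array([[3.0, 1.0], [1.0, 2.0]])
    assert np.allclose(endpoint_stiffness(K, np.eye(2)), K)


def test_endpoint_maps_singular_configuration_raises():
    params = ArmParams2Dof()
    with pytest.raises(ConfigurationError):
        endpoint_maps(params, np.array([0.5, 0.0]))  # elbow fully extended
    with pytest.raises(ConfigurationError):
        inverse_kinematics(params, (2.0, 2.0))  # out of the workspace


def test_two_joint_stiffness_increases_under_cocontraction(arm_plant):
    q = inverse_kinematics(ArmParams2Dof(), (0.0, 0.45))
    x = np.concatenate([q, [0.0, 0.0]])
    K0 = joint_stiffness(arm_plant, x, np.zeros(6))
    K1 = joint_stiffness(arm_plant, x, np.full(6, 0.5))
    for K in (K0, K1):
        assert np.allclose(K, K.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(K) > 0)
    assert np.all(np.linalg.eigvalsh(K1 - K0) > 0)


def test_invalid_parameters_rejected():
    with pytest.raises(ConfigurationError):
        PendulumParams(I=-1.0)
    with pytest.raises(ConfigurationError):
        JointImpedanceParams(I=0.0)
    with pytest.raises(ConfigurationError):
        MuscleParams1Dof(k=-5.0)
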