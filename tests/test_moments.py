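"""Moment propagation: degenerate closed forms, exactness for bilinear
systems against Euler-Maruyama sampling, and the expected-cost reduction."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import sooc
from sooc.moments import ValidationError
from sooc.simulate import compare_moments, euler_maruyama_ensemble


def test_zero_noise_propagation_matches_deterministic_ode(toy_bilinear):
    sys = toy_bilinear["system"]
    quiet = sooc.BilinearSystem(
        A=sys.A, B=sys.B, N=sys.N, diffusion=np.zeros((2, 1))
    )
    t = np.linspace(0, 2, 41)
    u = np.column_stack([0.3 * np.sin(t), 0.1 * np.cos(t)])
    m0 = np.array([0.5, -0.2])
    path = sooc.propagate_moments_bilinear(quiet, u, m0, np.zeros((2, 2)), t)
    assert np.allclose(path.cov, 0.0, atol=1e-12)

    def rhs(s, x):
        us = np.array([np.interp(s, t, u[:, j]) for j in range(2)])
        return quiet.dynamics.drift(x, us)

    ode = solve_ivp(rhs, (0, 2), m0, t_eval=t, rtol=1e-10, atol=1e-12)
    assert np.allclose(path.mean, ode.y.T, atol=1e-6)


def test_pure_brownian_covariance_grows_linearly(brownian):
    sys = brownian["system"]
    t = np.linspace(0, 3, 31)
    P0 = np.diag([0.2, 0.1])
    path = sooc.propagate_moments_bilinear(
        sys, np.zeros((31, 1)), np.zeros(2), P0, t
    )
    for k, tk in enumerate(t):
        assert np.allclose(
            path.cov[k], P0 + tk * brownian["GGT"], atol=1e-8
        )


def test_bilinear_moments_match_monte_carlo_ensemble():
    """The mean/covariance ODEs are exact for the antagonist-pendulum
    bilinear system: sample moments agree to within Monte-Carlo error."""
    sys = sooc.hogan_pendulum(linearized=True)
    t = np.linspace(0, 2.0, 21)
    u = np.full((21, 2), 2.0)  # stabilizing co-contraction
    path = sooc.propagate_moments_bilinear(
        sys, u, np.zeros(2), np.zeros((2, 2)), t
    )
    ens = euler_maruyama_ensemble(
        sys, u, np.zeros(2), t, n_paths=10_000, seed=7, store_paths=False
    )
    report = compare_moments(ens, path, z_threshold=4.0)
    assert ens.n_divergent == 0
    assert report["passed"], f"max |z| = {report['max_abs_z']:.2f}"


def test_linearized_equals_bilinear_for_linear_drift(toy_bilinear):
    sys = toy_bilinear["system"]
    linear = sooc.BilinearSystem(
        A=sys.A, B=sys.B, N=[], diffusion=np.array([[0.0], [0.2]])
    )
    t = np.linspace(0, 1.5, 31)
    u = np.column_stack([np.sin(t), np.cos(t)])
    m0 = np.array([0.1, 0.0])
    P0 = np.diag([0.01, 0.02])
    a = sooc.propagate_moments_bilinear(linear, u, m0, P0, t, method="rk4")
    b = sooc.propagate_moments_linearized(
        sooc.NonlinearPlant(dynamics=linear.dynamics), u, m0, P0, t,
        method="rk4",
    )
    assert np.allclose(a.mean, b.mean, atol=1e-10)
    assert np.allclose(a.cov, b.cov, atol=1e-10)


def test_linear_plant_covariance_independent_of_control(toy_bilinear):
    """Without control-state coupling (N = 0) and with control-independent
    noise, the covariance cannot be influenced by the control: the
    stochastic problem collapses onto the deterministic one."""
    sys = toy_bilinear["system"]
    linear = sooc.BilinearSystem(
        A=sys.A, B=sys.B, N=[], diffusion=np.array([[0.0], [0.2]])
    )
    t = np.linspace(0, 2, 41)
    P0 = np.diag([0.05, 0.01])
    m0 = np.zeros(2)
    pa = sooc.propagate_moments_bilinear(
        linear, np.zeros((41, 2)), m0, P0, t
    )
    pb = sooc.propagate_moments_bilinear(
        linear, np.column_stack([np.sin(3 * t), np.cos(t)]), m0, P0, t
    )
    assert np.allclose(pa.cov, pb.cov, atol=1e-8)
    assert not np.allclose(pa.mean, pb.mean, atol=1e-3)


def test_statistical_linearization_accuracy_small_noise():
    """Cubic scalar plant dx = (-x^3 + u) dt + sigma dW: the Gaussian
    closure reproduces Euler-Maruyama moments for small noise."""
    import sympy as sp

    from sooc._symbolic import SymbolicDynamics

    x, u = sp.symbols("x u", real=True)
    dyn = SymbolicDynamics(
        "cubic", (x,), (u,), sp.Matrix([-(x**3) + u]), sp.Matrix([[0.01]])
    )
    plant = sooc.NonlinearPlant(dynamics=dyn)
    t = np.linspace(0, 1, 21)
    U = np.full((21, 1), 0.5)
    m0, P0 = np.array([1.0]), np.zeros((1, 1))
    path = sooc.propagate_moments_linearized(plant, U, m0, P0, t)
    # small dt: with sigma = 0.01 the 3-SE band is so tight that the O(dt)
    # Euler-Maruyama bias would otherwise dominate the comparison
    ens = euler_maruyama_ensemble(
        plant, U, m0, t, n_paths=30_000, seed=3, dt_max=2.5e-4,
        store_paths=False,
    )
    report = compare_moments(ens, path, z_threshold=4.0)
    assert report["passed"], f"max |z| = {report['max_abs_z']:.2f}"


def test_expected_cost_effort_only_and_trace_terms():
    R = np.eye(2)
    t = np.linspace(0, 1, 101)
    U = np.column_stack([np.full(101, 0.3), np.zeros(101)])
    path = sooc.MomentPath(
        t, np.zeros((101, 2)), np.tile(np.diag([0.5, 0.25]), (101, 1, 1))
    )
    c = sooc.expected_cost(sooc.QuadraticCost(R=R), path, U)
    assert c.total == pytest.approx(0.09, rel=1e-12)

    c2 = sooc.expected_cost(
        sooc.QuadraticCost(R=R, Q=np.eye(2)), path, np.zeros((101, 2))
    )
    # u = 0, m = 0: only the running trace term, (tf - t0) * trace(P)
    assert c2.total == pytest.approx(0.75, rel=1e-12)
    assert c2.effort == 0.0


def test_expected_cost_equals_monte_carlo_expectation(toy_bilinear):
    """The deterministic reduction of E[int u'Ru + x'Qx dt + x_f'Qf x_f]
    equals the sampled expectation over SDE realizations."""
    sys = toy_bilinear["system"]
    t = np.linspace(0, 1.5, 31)
    rng = np.random.default_rng(5)
    U = 0.4 + 0.2 * rng.standard_normal((31, 2))
    m0 = np.array([0.3, 0.0])
    cost = sooc.QuadraticCost(
        R=np.eye(2), Q=np.diag([2.0, 0.5]), Qf=np.diag([5.0, 1.0])
    )
    path = sooc.propagate_moments_bilinear(sys, U, m0, np.zeros((2, 2)), t)
    predicted = sooc.expected_cost(cost, path, U).total

    ens = euler_maruyama_ensemble(
        sys, U, m0, t, n_paths=20_000, seed=11, dt_max=2e-4
    )
    X = ens.paths
    state_q = np.einsum("pti,ij,ptj->pt", X, cost.Q, X)
    run = np.trapezoid(
        np.einsum("ti,ij,tj->t", U, cost.R, U)[None, :] + state_q, t, axis=1
    )
    term = np.einsum("pi,ij,pj->p", X[:, -1], cost.Qf, X[:, -1])
    samples = run + term
    se = samples.std(ddof=1) / np.sqrt(len(samples))
    assert abs(samples.mean() - predicted) < 3 * se


def test_diffusion_outer_values(kk1_plant):
    sys = sooc.hogan_pendulum(linearized=True)
    out = sooc.diffusion_outer(sys, u=[1.0, 1.0])
    assert np.allclose(out, [[0.0, 0.0], [0.0, 0.01]])

    quiet = sooc.BilinearSystem(
        A=np.zeros((2, 2)), B=np.zeros((2, 1)), N=[],
        diffusion=np.zeros((2, 1)),
    )
    assert np.allclose(sooc.diffusion_outer(quiet, u=[0.0]), 0.0)
    # co-contraction-aware noise vanishes at zero activation
    assert np.allclose(
        sooc.diffusion_outer(kk1_plant, u=[0.0, 0.0]), 0.0
    )


def test_diffusion_outer_state_dependent_requires_mean(arm_plant):
    with pytest.raises(ValidationError):
        sooc.diffusion_outer(arm_plant, u=np.zeros(6))
    out = sooc.diffusion_outer(
        arm_plant, u=np.zeros(6), m=np.array([1.3, 1.9, 0.0, 0.0])
    )
    assert out.shape == (4, 4)
    assert np.all(np.linalg.eigvalsh(out) >= -1e-12)


def test_state_moments_validation():
    with pytest.raises(ValidationError):
        sooc.StateMoments(np.zeros(2), np.array([[1.0, 0.5], [0.4, 1.0]]))
    with pytest.raises(ValidationError):
        sooc.StateMoments(np.zeros(2), np.diag([1.0, -0.5]))
    ok = sooc.StateMoments(np.zeros(2), np.diag([1.0, 0.0]))
    assert ok.std[1] == 0.0
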