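"""Direct transcription: NLP shape, LQ oracle, zero-noise equivalence,
defect consistency against the standalone propagator, and solver
robustness."""

import numpy as np
import pytest

import sooc
from sooc.experiments import riccati_lq_cost
from sooc.moments import ConfigurationError
from sooc.transcription import (
    OCProblem,
    SolverOptions,
    build_equivalent_doc,
    restart_stability_check,
    solve,
)


def _lq_problem(lq, noise=None):
    sys = lq["system"]
    if noise is not None:
        sys = sooc.BilinearSystem(
            A=lq["A"], B=lq["B"], N=[np.zeros((2, 2))], diffusion=noise
        )
    cost = sooc.QuadraticCost(R=lq["R"], Q=lq["Q"], Qf=lq["Qf"])
    return OCProblem(
        plant=sys,
        cost=cost,
        t_f=lq["t_f"],
        m0=lq["x0"],
        P0=np.zeros((2, 2)),
    )


def test_nlp_counting(toy_bilinear):
    """n = 2 moment states are 2 means + 3 covariance entries; with p
    controls each of the N nodes carries p + 5 variables and each of the
    N - 1 intervals 5 defect rows."""
    sys = toy_bilinear["system"]
    problem = OCProblem(
        plant=sys,
        cost=sooc.QuadraticCost(R=np.eye(2)),
        t_f=1.0,
        m0=np.zeros(2),
        P0=np.zeros((2, 2)),
    )
    nlp = build_equivalent_doc(problem, SolverOptions(n_nodes=50))
    assert nlp.nw == 50 * (2 + 2 + 3)
    assert nlp.n_defects == 49 * 5
    # boundary-fixed: 5 initial moment entries
    assert nlp.n_free_variables == nlp.nw - 5


def test_effort_only_cost_yields_zero_control(lq):
    sys = lq["system"]
    problem = OCProblem(
        plant=sys,
        cost=sooc.QuadraticCost(R=np.eye(1)),
        t_f=1.0,
        m0=np.zeros(2),
        P0=np.zeros((2, 2)),
        control_bounds=(np.array([0.0]), np.array([1.0])),
    )
    traj = solve(problem, SolverOptions(n_nodes=30))
    assert traj.status == "converged"
    assert traj.objective == pytest.approx(0.0, abs=1e-8)
    # the SQP stops once the effort is numerically zero; controls sit at
    # the guess magnitude or below
    assert np.all(traj.u <= 0.02)


def test_zero_noise_lq_matches_riccati_oracle(lq):
    """Without noise the moment problem collapses onto the deterministic
    LQ problem, whose optimal cost follows from backward Riccati
    integration."""
    problem = _lq_problem(lq)
    traj = solve(problem, SolverOptions(n_nodes=100, nlp_tolerance=1e-12))
    assert traj.status == "converged"
    assert np.allclose(traj.cov, 0.0, atol=1e-10)
    oracle = riccati_lq_cost(
        lq["A"], lq["B"], lq["R"], lq["Q"], lq["Qf"], lq["x0"], lq["t_f"]
    )
    # trapezoidal discretization error at h = 0.02 is O(h^2)
    assert traj.objective == pytest.approx(oracle, rel=5e-4)


def test_constant_noise_shifts_lq_cost_by_trace_term(lq):
    """With control-independent noise the optimal control is unchanged and
    the optimal cost grows by the (control-independent) covariance cost."""
    quiet = solve(_lq_problem(lq), SolverOptions(n_nodes=60))
    noisy = solve(
        _lq_problem(lq, noise=np.array([[0.0], [0.3]])),
        SolverOptions(n_nodes=60),
    )
    assert noisy.status == "converged"
    assert np.allclose(noisy.u, quiet.u, atol=1e-4)
    path = sooc.propagate_moments_bilinear(
        _lq_problem(lq, noise=np.array([[0.0], [0.3]])).plant,
        noisy.u, lq["x0"], np.zeros((2, 2)), noisy.t_grid,
    )
    cov_cost = sooc.expected_cost(
        sooc.QuadraticCost(R=lq["R"], Q=lq["Q"], Qf=lq["Qf"]),
        path, noisy.u,
    )
    assert noisy.objective == pytest.approx(
        quiet.objective + cov_cost.covariance + cov_cost.terminal_cov,
        rel=1e-3,
    )


def test_defect_consistency_with_standalone_propagator(solves):
    """Re-integrating the moment ODEs under the returned open-loop control
    reproduces the NLP's terminal moments up to discretization error."""
    traj = solves.trajectory("missenard_normal")
    problem = OCProblem.from_task(
        traj.bundle["plant"], traj.bundle["task"]
    )
    path = sooc.propagate_moments_linearized(
        traj.bundle["plant"], traj.u, problem.m0, problem.P0, traj.t_grid
    )
    assert np.allclose(path.mean[-1], traj.mean[-1], atol=2e-3)
    ep_nlp = np.sqrt(traj.cov[-1, 0, 0])
    ep_ode = np.sqrt(path.cov[-1, 0, 0])
    assert ep_ode == pytest.approx(ep_nlp, rel=5e-3)


def test_reported_cost_matches_recomputation(solves):
    traj = solves.trajectory("missenard_normal")
    assert traj.cost_breakdown.total == pytest.approx(
        traj.objective, rel=1e-6
    )


def test_restart_stability_convex_case(lq):
    report = restart_stability_check(
        _lq_problem(lq),
        SolverOptions(n_nodes=40),
        n_restarts=3,
        seed=0,
    )
    assert all(s == "converged" for s in report["statuses"])
    assert report["spread"] <= 1e-6
    assert not report["multimodal"]


def test_infeasible_terminal_condition_reported_not_raised(lq):
    sys = lq["system"]
    problem = OCProblem(
        plant=sys,
        cost=sooc.QuadraticCost(R=np.eye(1)),
        t_f=0.5,
        m0=np.zeros(2),
        P0=np.zeros((2, 2)),
        terminal_mean=np.array([5.0, 0.0]),
        control_bounds=(np.array([0.0]), np.array([0.0])),  # pinned input
    )
    traj = solve(problem, SolverOptions(n_nodes=20, max_iterations=60))
    assert traj.status in ("infeasible", "max_iter")
    report = restart_stability_check(
        problem, SolverOptions(n_nodes=20, max_iterations=40), n_restarts=2
    )
    assert all(s != "converged" for s in report["statuses"])


def test_option_validation():
    with pytest.raises(ConfigurationError):
        SolverOptions(n_nodes=5)
    with pytest.raises(ConfigurationError):
        SolverOptions(scheme="hermite-simpson")
    with pytest.raises(ConfigurationError):
        SolverOptions(method="ipopt")


def test_trajectory_roundtrip(tmp_path, solves):
    traj = solves.trajectory("missenard_normal")
    out = traj.save(tmp_path / "run")
    import json

    import pandas as pd

    df = pd.read_csv(out / "trajectory.csv")
    assert list(df.columns) == [
        "t", "u_1", "u_2", "m_1", "m_2", "P_11", "P_12", "P_22",
    ]
    man = json.loads((out / "manifest.json").read_text())
    assert man["status"] == "converged"
    assert man["objective"] == pytest.approx(traj.objective)
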