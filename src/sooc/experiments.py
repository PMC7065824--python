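"""Config-driven experiment presets: posture maintenance, single-joint
reaches (joint-level and muscle-level), and two-joint reaches in a
divergent force field, each bundling a plant, a task and solver options.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as _metrics
from .moments import BilinearSystem, ConfigurationError
from .plants import (
    ArmParams2Dof,
    DivergentField,
    JointImpedanceParams,
    MuscleParams1Dof,
    PendulumParams,
    arm_jacobian,
    hogan_pendulum,
    joint_impedance_plant,
    kk_onejoint,
    kk_twojoint,
)
from .simulate import compare_moments, euler_maruyama_ensemble
from .tasks import (
    bennett_cost,
    burdet_cost,
    hogan_posture_cost,
    missenard_cost,
)
from .transcription import OCProblem, SolverOptions, solve

__all__ = [
    "PRESETS",
    "build_preset",
    "run_experiment",
    "make_table1",
    "fixture_generator",
    "load_config",
]


# ---------------------------------------------------------------------------
# Preset builders
# ---------------------------------------------------------------------------

def _hogan(loaded=False, noise_scale=1.0, t_f=5.0, n_nodes=100):
    params = PendulumParams(m_load=2.268 if loaded else 0.0)
    sys = hogan_pendulum(params, linearized=True,
                         noise=(0.0, 0.1 * noise_scale))
    task = hogan_posture_cost(t_f=t_f)
    task.control_bounds = (np.zeros(2), np.full(2, np.inf))
    # stabilizing guess: co-contraction 20% above the divergence level, so
    # the propagated covariance guess stays finite on this unstable plant
    u_guess = 0.6 * params.gravity_torque_coeff / params.K
    return {
        "plant": sys,
        "task": task,
        "options": SolverOptions(
            n_nodes=n_nodes, guess_control=u_guess, nlp_tolerance=1e-8,
            max_iterations=800,
        ),
        "kind": "posture",
    }


def _bennett(t_f=0.75, q_var=1e4, alpha=1.0, q_v=0.01, amplitude=1.0,
             n_nodes=60):
    params = JointImpedanceParams(I=0.072, b=0.0)
    plant = joint_impedance_plant(params)
    task = bennett_cost(plant, q_var=q_var, alpha=alpha, q_v=q_v, t_f=t_f,
                        amplitude=amplitude)

    def guess(t, I=params.I, A=amplitude, T=t_f):
        # minimum-effort rigid-body torque for the reference reach, plus a
        # moderate constant stiffness command
        return np.array([I * (6 * A / T**2) * (1 - 2 * t / T), 5.0])

    return {
        "plant": plant,
        "task": task,
        "options": SolverOptions(
            n_nodes=n_nodes,
            guess_control=guess,
            initial_guess_policy="propagate_full",
            # the interior-point method handles the sqrt(kappa) damping and
            # the cyclic covariance coupling better than SQP here
            method="trust-constr",
            nlp_tolerance=1e-6,
            max_iterations=3000,
        ),
        "kind": "joint_reach",
    }


def _missenard(t_f=0.475, q_var=50.0, d=4.0, n_nodes=100):
    plant = kk_onejoint(MuscleParams1Dof(), noise_d=d)
    task = missenard_cost(q_var=q_var, t_f=t_f)
    return {
        "plant": plant,
        "task": task,
        "options": SolverOptions(n_nodes=n_nodes),
        "kind": "reach",
    }


def _burdet(q_var=1e4, beta=40.0, sigma=0.025, t_f=0.75, n_nodes=40):
    params = ArmParams2Dof()
    field = DivergentField(beta=beta) if beta else None
    plant = kk_twojoint(params, field=field, sigma=(sigma, sigma))
    task = burdet_cost(plant, q_var=q_var, t_f=t_f)
    return {
        "plant": plant,
        "task": task,
        "options": SolverOptions(
            n_nodes=n_nodes, method="hybrid", max_iterations=4000,
            polish_iterations=300, nlp_tolerance=1e-9,
        ),
        "kind": "arm_reach",
    }


def _point_to_line(direction="forward", q_var=1e4, sigma=0.1, n_nodes=40):
    params = ArmParams2Dof()
    plant = kk_twojoint(params, field=None, sigma=(sigma, sigma))
    if direction == "forward":
        target, normal, t_f = (0.0, 0.55), (0.0, 1.0), 0.75
    elif direction == "leftward":
        target, normal, t_f = (-0.25, 0.30), (1.0, 0.0), 0.55
    else:
        raise ConfigurationError(f"unknown direction {direction!r}")
    task = burdet_cost(
        plant, q_var=q_var, t_f=t_f, smoothness_on=True,
        target_xy=target, line_normal=normal,
    )
    return {
        "plant": plant,
        "task": task,
        "options": SolverOptions(
            n_nodes=n_nodes, method="hybrid", max_iterations=4000,
            polish_iterations=300, nlp_tolerance=1e-9,
        ),
        "kind": "arm_reach",
        "line_normal": np.asarray(normal),
    }


PRESETS = {
    "hogan_unloaded": lambda **kw: _hogan(loaded=False, **kw),
    "hogan_loaded": lambda **kw: _hogan(loaded=True, **kw),
    "hogan_noise5x": lambda **kw: _hogan(loaded=False, noise_scale=5.0, **kw),
    "bennett_cyclic": _bennett,
    "missenard_normal": lambda **kw: _missenard(
        **{"t_f": 0.475, "q_var": 50.0, **kw}),
    "missenard_fast": lambda **kw: _missenard(
        **{"t_f": 0.400, "q_var": 50.0, **kw}),
    "missenard_cocontract": lambda **kw: _missenard(
        **{"t_f": 0.400, "q_var": 500.0, **kw}),
    "missenard_lowvar_475": lambda **kw: _missenard(
        **{"t_f": 0.475, "q_var": 1.0, **kw}),
    "missenard_lowvar_400": lambda **kw: _missenard(
        **{"t_f": 0.400, "q_var": 1.0, **kw}),
    "burdet_nf": lambda **kw: _burdet(**{"q_var": 0.0, "beta": 0.0, **kw}),
    "burdet_df": lambda **kw: _burdet(**{"q_var": 1e4, "beta": 40.0, **kw}),
    "burdet_df_novar": lambda **kw: _burdet(
        **{"q_var": 0.0, "beta": 40.0, **kw}),
    "burdet_df_highnoise": lambda **kw: _burdet(
        **{"q_var": 1e4, "beta": 40.0, "sigma": 0.05, **kw}),
    "burdet_df_strongfield": lambda **kw: _burdet(
        **{"q_var": 1e4, "beta": 80.0, **kw}),
    "point_to_line_forward": lambda **kw: _point_to_line("forward", **kw),
    "point_to_line_leftward": lambda **kw: _point_to_line("leftward", **kw),
}


def build_preset(name: str, **overrides) -> dict:
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[name](**overrides)


def load_config(path) -> dict:
    """YAML config: ``preset: <name>`` plus optional ``overrides`` (preset
    keyword arguments) and ``solver`` (SolverOptions fields)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "preset" not in cfg:
        raise ConfigurationError("config must be a mapping with a 'preset'")
    bundle = build_preset(cfg["preset"], **(cfg.get("overrides") or {}))
    solver = cfg.get("solver") or {}
    if solver:
        bundle["options"] = replace(bundle["options"], **solver)
    bundle["preset"] = cfg["preset"]
    return bundle


# ---------------------------------------------------------------------------
# Running experiments
# ---------------------------------------------------------------------------

def _experiment_metrics(bundle, traj) -> dict:
    kind = bundle["kind"]
    out = {
        "status": traj.status,
        "objective": traj.objective,
        "effort": _metrics.effort_integral(traj.u, traj.t_grid),
    }
    plant = bundle["plant"]
    if kind == "reach":
        out.update(_metrics.reach_summary(traj))
        out["IC_min_over_max_pct"] = _metrics.cocontraction_index(
            traj.u[:, 0], traj.u[:, 1], traj.t_grid,
            definition="min_over_max",
        )
    elif kind == "posture":
        stiff = _metrics.stiffness_summary(traj, plant)
        out["K_mean"] = float(stiff["K_mean"][0, 0])
        out["K_min"] = float(stiff["K"][:, 0, 0].min())
        out["K_t"] = stiff["K"][:, 0, 0]
    elif kind == "joint_reach":
        stiff = _metrics.stiffness_summary(traj, plant)
        out["K_t"] = stiff["K"][:, 0, 0]
        out["K_mean"] = float(stiff["K_mean"][0, 0])
        tau_mean = float(
            np.trapezoid(np.abs(traj.u[:, 0]), traj.t_grid)
            / (traj.t_grid[-1] - traj.t_grid[0])
        )
        out["abs_torque_mean"] = tau_mean
        out["PV_deg_s"] = _metrics.peak_velocity(traj)
    elif kind == "arm_reach":
        params = plant.meta["arm_params"]
        Jf = arm_jacobian(params, traj.mean[-1, :2])
        Pq = traj.cov[-1][:2, :2]
        S_task = Jf @ Pq @ Jf.T
        out["EPstd_x_cm"] = float(np.sqrt(max(S_task[0, 0], 0)) * 100)
        out["EPstd_y_cm"] = float(np.sqrt(max(S_task[1, 1], 0)) * 100)
        out["endpoint_cov_task"] = S_task
        stiff = _metrics.stiffness_summary(traj, plant)
        out["Sxx_mean"] = float(stiff["S_mean"][0, 0])
        out["Syy_mean"] = float(stiff["S_mean"][1, 1])
    return out


def run_experiment(
    preset_or_config,
    out_dir=None,
    seed: int = 0,
    n_paths: int = 0,
    dt_max: float = 1e-3,
    **overrides,
) -> dict:
    """Solve a preset (or a config mapping), compute its metrics, and
    optionally validate by Monte-Carlo simulation of the original SDE."""
    if isinstance(preset_or_config, str) and preset_or_config in PRESETS:
        bundle = build_preset(preset_or_config, **overrides)
        bundle["preset"] = preset_or_config
    elif isinstance(preset_or_config, dict):
        bundle = preset_or_config
    else:
        bundle = load_config(preset_or_config)
    options = replace(bundle["options"], random_seed=seed)
    problem = OCProblem.from_task(bundle["plant"], bundle["task"])
    traj = solve(problem, options)
    result = {
        "trajectory": traj,
        "metrics": _experiment_metrics(bundle, traj),
        "bundle": bundle,
        "seed": seed,
    }
    if n_paths > 0:
        dyn = bundle["plant"].dynamics
        P0 = problem.P0 if problem.P0 is not None else traj.cov[0]
        ens = euler_maruyama_ensemble(
            bundle["plant"],
            traj.u,
            (problem.m0, P0),
            traj.t_grid,
            n_paths=n_paths,
            seed=seed,
            dt_max=dt_max,
            store_paths=False,
        )
        result["ensemble"] = ens
        result["moment_check"] = compare_moments(ens, traj.moments)
    if out_dir is not None:
        out = Path(out_dir)
        traj.save(out, extra_manifest={"seed": seed,
                                       "preset": bundle.get("preset", "")})
        clean = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in result["metrics"].items()
        }
        (out / "metrics.json").write_text(
            json.dumps(clean, indent=2, default=float) + "\n"
        )
    return result


TABLE1_ROWS = [
    (0.475, 50.0),
    (0.400, 50.0),
    (0.400, 500.0),
    (0.475, 1.0),
    (0.400, 1.0),
]


def make_table1(out_dir=None, n_nodes: int = 100, seed: int = 0,
                ic_definition: str = "overlap") -> pd.DataFrame:
    """Run the five (t_f, q_var) single-joint reaching conditions and
    tabulate EPstd, PV, effort (x 1e-2) and the co-contraction index."""
    rows = []
    for t_f, q_var in TABLE1_ROWS:
        try:
            res = run_experiment(
                "missenard_normal", seed=seed, t_f=t_f, q_var=q_var,
                n_nodes=n_nodes,
            )
            traj = res["trajectory"]
            summ = _metrics.reach_summary(traj, ic_definition=ic_definition)
            rows.append(
                {
                    "tf_ms": round(t_f * 1000),
                    "EPstd_deg": summ["EPstd_deg"],
                    "PV_deg_s": summ["PV_deg_s"],
                    "q_var": q_var,
                    "Effort_x1e-2": summ["Effort"] * 100,
                    "IC_pct": summ["IC_pct"],
                    "status": traj.status,
                }
            )
        except Exception as exc:  # pragma: no cover - defensive
            rows.append(
                {"tf_ms": round(t_f * 1000), "q_var": q_var,
                 "status": f"error: {exc}"}
            )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "table1.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# Analytic fixtures for the test-suite
# ---------------------------------------------------------------------------

def fixture_generator(kind: str, seed: int = 0) -> dict:
    """Small systems with closed-form moments/optimal costs."""
    rng = np.random.default_rng(seed)
    if kind == "ou_process":
        sys = BilinearSystem(
            A=[[-1.0]], B=[[1.0]], N=[np.zeros((1, 1))],
            diffusion=[[1.0]], name="ou",
        )
        return {
            "system": sys,
            "stationary_var": 0.5,  # sigma^2 / (2*theta)
            "var_at": lambda t, v0=0.0: 0.5 + (v0 - 0.5) * np.exp(-2 * t),
        }
    if kind == "pure_brownian":
        G = np.array([[0.3], [0.4]])
        sys = BilinearSystem(
            A=np.zeros((2, 2)), B=np.zeros((2, 1)), N=[np.zeros((2, 2))],
            diffusion=G, name="brownian",
        )
        return {"system": sys, "GGT": G @ G.T}
    if kind == "lq_system":
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        B = np.array([[0.0], [1.0]])
        sys = BilinearSystem(
            A=A, B=B, N=[np.zeros((2, 2))],
            diffusion=np.zeros((2, 1)), name="lq",
        )
        return {
            "system": sys,
            "A": A,
            "B": B,
            "R": np.array([[1.0]]),
            "Q": np.diag([4.0, 1.0]),
            "Qf": np.diag([10.0, 2.0]),
            "x0": np.array([1.0, 0.0]),
            "t_f": 2.0,
        }
    if kind == "toy_bilinear":
        N1 = np.array([[0.0, 0.0], [-1.5, 0.0]])
        sys = BilinearSystem(
            A=np.array([[0.0, 1.0], [-2.0, -1.0]]),
            B=np.array([[0.0, 0.0], [1.0, -1.0]]),
            N=[N1, N1],
            diffusion=np.array([[0.0], [0.2]]),
            name="toy_bilinear",
        )
        return {"system": sys}
    raise ConfigurationError(f"unknown fixture kind {kind!r}")


def riccati_lq_cost(A, B, R, Q, Qf, x0, t_f) -> float:
    """Finite-horizon LQR optimal cost by backward Riccati integration
    (the independent oracle for zero-noise solves)."""
    from scipy.integrate import solve_ivp

    n = A.shape[0]
    Rinv = np.linalg.inv(R)

    def rhs(t, s):
        S = s.reshape(n, n)
        dS = -(A.T @ S + S @ A - S @ B @ Rinv @ B.T @ S + Q)
        return dS.ravel()

    sol = solve_ivp(
        rhs, (t_f, 0.0), np.asarray(Qf, dtype=float).ravel(),
        rtol=1e-10, atol=1e-12, dense_output=True,
    )
    S0 = sol.y[:, -1].reshape(n, n)
    return float(x0 @ S0 @ x0)
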