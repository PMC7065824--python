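"""Summary metrics of solved reaching/posture tasks: peak velocity,
terminal endpoint standard deviation, co-contraction index, effort, and
stiffness summaries.  All reports use degrees / deg/s / cm / N/m; internal
computation is in radians."""

from __future__ import annotations

import numpy as np

from .moments import ConfigurationError, ValidationError
from .plants import arm_jacobian, endpoint_stiffness, joint_stiffness

__all__ = [
    "peak_velocity",
    "endpoint_std",
    "cocontraction_index",
    "effort_integral",
    "stiffness_summary",
    "reach_summary",
]

RAD2DEG = 180.0 / np.pi


def peak_velocity(trajectory, velocity_index: int = 1) -> float:
    """Maximum of |mean angular velocity| in deg/s."""
    mean = np.asarray(getattr(trajectory, "mean", trajectory), dtype=float)
    return float(np.max(np.abs(mean[:, velocity_index])) * RAD2DEG)


def endpoint_std(
    P_f: np.ndarray,
    projector: np.ndarray | None = None,
    degrees: bool = True,
) -> float:
    """sqrt of the projected terminal positional variance.

    1-dof: ``projector=None`` picks P[0,0] (joint angle), reported in deg.
    2-dof: pass a row ``projector`` (e.g. the x-row of the hand Jacobian)
    to get the Cartesian std along that axis, reported in the projector's
    units (m if J is in m/rad).
    """
    P_f = np.asarray(P_f, dtype=float)
    if projector is None:
        var = P_f[0, 0]
    else:
        v = np.asarray(projector, dtype=float).ravel()
        var = float(v @ P_f[: v.size, : v.size] @ v)
    if var < -1e-10:
        raise ValidationError(f"projected variance {var:.3e} < 0")
    std = np.sqrt(max(var, 0.0))
    return float(std * RAD2DEG) if degrees else float(std)


def cocontraction_index(
    u1,
    u2,
    t=None,
    definition: str = "overlap",
) -> float:
    """Co-contraction index (%) of an antagonist activation pair.

    definitions:
      overlap      100 * 2 * int(min(u1,u2)) / int(u1 + u2)
      min_over_max 100 * int(min(u1,u2)) / int(max(u1,u2))

    Both are 100 for identical activations and 0 for strictly reciprocal
    ones, and are invariant under common positive rescaling.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if np.any(u1 < -1e-12) or np.any(u2 < -1e-12):
        raise ValidationError("activations must be nonnegative")
    t = np.arange(len(u1), dtype=float) if t is None else np.asarray(t)
    lo = np.trapezoid(np.minimum(u1, u2), t)
    if definition == "overlap":
        denom = np.trapezoid(u1 + u2, t)
    elif definition == "min_over_max":
        denom = np.trapezoid(np.maximum(u1, u2), t)
    else:
        raise ConfigurationError(f"unknown IC definition {definition!r}")
    if denom <= 1e-300:
        import warnings

        warnings.warn("both activations are identically zero; IC := 0")
        return 0.0
    scale = 2.0 if definition == "overlap" else 1.0
    return float(100.0 * scale * lo / denom)


def effort_integral(u_traj, t, R: np.ndarray | None = None) -> float:
    """Trapezoidal integral of u' R u (R defaults to identity)."""
    U = np.asarray(u_traj, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    t = np.asarray(t, dtype=float)
    if len(t) != U.shape[0]:
        raise ValidationError("control and time grids differ in length")
    R = np.eye(U.shape[1]) if R is None else np.asarray(R, dtype=float)
    return float(np.trapezoid(np.einsum("ki,ij,kj->k", U, R, U), t))


def stiffness_summary(trajectory, plant) -> dict:
    """Joint (and, for the two-joint arm, endpoint) stiffness along the
    mean trajectory, with time averages."""
    t = trajectory.t_grid
    K = np.array(
        [
            joint_stiffness(plant, trajectory.mean[k], trajectory.u[k])
            for k in range(len(t))
        ]
    )
    out = {"t": t, "K": K, "K_mean": np.trapezoid(K, t, axis=0) / (t[-1] - t[0])}
    params = getattr(plant, "meta", {}).get("arm_params")
    if params is not None:
        S, skipped = [], []
        for k in range(len(t)):
            q = trajectory.mean[k, :2]
            J = arm_jacobian(params, q)
            if abs(np.linalg.det(J)) < 1e-10:
                skipped.append(k)
                S.append(np.full((2, 2), np.nan))
                continue
            S.append(endpoint_stiffness(K[k], J))
        S = np.array(S)
        out["S"] = S
        out["S_mean"] = np.nanmean(S, axis=0)
        out["skipped_nodes"] = skipped
    return out


def reach_summary(
    trajectory,
    ic_definition: str = "overlap",
    projector: np.ndarray | None = None,
) -> dict:
    """Scalar summary of a 1-dof reach solve (the table-row quantities)."""
    t = trajectory.t_grid
    U = trajectory.u
    return {
        "EPstd_deg": endpoint_std(trajectory.cov[-1], projector),
        "PV_deg_s": peak_velocity(trajectory),
        "Effort": effort_integral(U, t),
        "IC_pct": cocontraction_index(
            U[:, 0], U[:, 1], t, definition=ic_definition
        ),
    }
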