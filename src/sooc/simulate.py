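"""Euler-Maruyama ensembles of the original SDE under a fixed open-loop
control, used to validate the moment propagation (the bilinear moment ODEs
are exact, so sample moments must agree to within Monte-Carlo error)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moments import ConfigurationError, MomentPath, ValidationError

__all__ = ["EnsembleResult", "euler_maruyama_ensemble", "compare_moments"]

DIVERGENCE_THRESHOLD = 1e6


@dataclass
class EnsembleResult:
    t: np.ndarray
    paths: np.ndarray | None       # (n_paths, n_times, n) or None if thinned
    sample_mean: np.ndarray        # (n_times, n)
    sample_cov: np.ndarray         # (n_times, n, n)
    n_paths: int
    n_divergent: int
    divergence_times: np.ndarray
    seed: int

    @property
    def mean_se(self) -> np.ndarray:
        """Standard error of the sample mean, per time and state."""
        n = max(self.n_paths - self.n_divergent, 1)
        var = np.einsum("tii->ti", self.sample_cov)
        return np.sqrt(np.clip(var, 0, None) / n)


def _as_control(u_traj, t_grid, p):
    if callable(u_traj):
        return u_traj
    U = np.asarray(u_traj, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    if U.shape != (len(t_grid), p):
        raise ConfigurationError("control trajectory shape mismatch")
    return lambda t: np.array(
        [np.interp(t, t_grid, U[:, j]) for j in range(p)]
    )


def euler_maruyama_ensemble(
    plant,
    u_traj,
    x0,
    t_grid,
    n_paths: int = 500,
    seed: int = 0,
    dt_max: float = 1e-3,
    store_paths: bool = True,
) -> EnsembleResult:
    """Simulate ``n_paths`` realizations with independent Gaussian
    increments; ``u`` is interpolated to the substeps.

    ``x0`` is either a state vector (deterministic start) or a tuple
    ``(m0, P0)`` to draw Gaussian initial conditions.  Paths that blow up
    (|state| > 1e6 or NaN) are excluded from the ensemble statistics and
    counted, with their first divergence time recorded.
    """
    dyn = plant.dynamics
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing")
    ufun = _as_control(u_traj, t_grid, dyn.p)
    rng = np.random.default_rng(seed)

    if isinstance(x0, tuple):
        m0, P0 = x0
        L = np.linalg.cholesky(
            np.asarray(P0, dtype=float) + 1e-15 * np.eye(dyn.n)
        )
        X = np.asarray(m0, dtype=float) + rng.standard_normal(
            (n_paths, dyn.n)
        ) @ L.T
    else:
        X = np.tile(np.asarray(x0, dtype=float), (n_paths, 1))

    n_times = len(t_grid)
    out = np.empty((n_paths, n_times, dyn.n))
    out[:, 0] = X
    alive = np.ones(n_paths, dtype=bool)
    t_div = np.full(n_paths, np.nan)

    for k in range(n_times - 1):
        t0, t1 = t_grid[k], t_grid[k + 1]
        nsub = max(1, int(np.ceil((t1 - t0) / dt_max)))
        dt = (t1 - t0) / nsub
        for s in range(nsub):
            t = t0 + s * dt
            u = np.broadcast_to(ufun(t), (n_paths, dyn.p))
            f = dyn.drift(X, u)
            G = dyn.diffusion(X, u)
            dW = rng.standard_normal((n_paths, dyn.m_noise)) * np.sqrt(dt)
            X = X + f * dt + np.einsum("pij,pj->pi", G, dW)
            bad = alive & (
                ~np.isfinite(X).all(axis=1)
                | (np.abs(X).max(axis=1) > DIVERGENCE_THRESHOLD)
            )
            if bad.any():
                t_div[bad] = t + dt
                alive &= ~bad
                X[bad] = 0.0  # frozen; excluded from statistics
        out[:, k + 1] = np.where(alive[:, None], X, np.nan)

    ok = alive
    n_div = int(n_paths - ok.sum())
    sel = out[ok] if ok.any() else out[:1] * np.nan
    mean = np.nanmean(sel, axis=0)
    dev = sel - mean[None]
    denom = max(ok.sum() - 1, 1)
    cov = np.einsum("pti,ptj->tij", np.nan_to_num(dev), np.nan_to_num(dev))
    cov /= denom
    return EnsembleResult(
        t=t_grid,
        paths=out if store_paths else None,
        sample_mean=mean,
        sample_cov=cov,
        n_paths=n_paths,
        n_divergent=n_div,
        divergence_times=t_div[~np.isnan(t_div)],
        seed=seed,
    )


def compare_moments(
    ensemble: EnsembleResult,
    predicted: MomentPath,
    z_threshold: float = 4.0,
) -> dict:
    """Standardized discrepancies between sample and predicted moments.

    Mean: z = (m_hat - m) / SE(m_hat).  Covariance: elementwise z using the
    Gaussian standard error SE(P_ij) ~ sqrt((P_ii P_jj + P_ij^2) / n).
    """
    if len(ensemble.t) != len(predicted.t) or not np.allclose(
        ensemble.t, predicted.t
    ):
        raise ValidationError("ensemble and prediction grids differ")
    n_eff = max(ensemble.n_paths - ensemble.n_divergent, 2)
    se_m = ensemble.mean_se
    floor = 1e-12
    z_mean = (ensemble.sample_mean - predicted.mean) / np.maximum(se_m, floor)
    Pii = np.einsum("tii->ti", predicted.cov)
    se_P = np.sqrt(
        (
            Pii[:, :, None] * Pii[:, None, :]
            + predicted.cov**2
        )
        / n_eff
    )
    z_cov = (ensemble.sample_cov - predicted.cov) / np.maximum(se_P, floor)
    # skip the initial deterministic point where both SEs vanish
    z_mean[0] = np.where(se_m[0] > floor, z_mean[0], 0.0)
    z_cov[0] = np.where(se_P[0] > floor, z_cov[0], 0.0)
    max_z = float(
        max(np.abs(z_mean).max(initial=0), np.abs(z_cov).max(initial=0))
    )
    return {
        "z_mean": z_mean,
        "z_cov": z_cov,
        "max_abs_z": max_z,
        "passed": bool(max_z < z_threshold),
        "z_threshold": z_threshold,
    }
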