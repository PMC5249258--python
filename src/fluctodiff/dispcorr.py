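"""Displacement autocorrelation function (DAF) and FBM reference curves.

The DAF probes the memory of increments of length Δ:

    C_Δ(t) = ⟨(x(t + Δ) - x(t)) (x(Δ) - x(0))⟩ / Δ²

For fractional Brownian motion with MSD exponent α the normalized DAF has
the exact stationary-increment form

    C_Δ(t)/C_Δ(0) = ((t + Δ)^α - 2 t^α + |t - Δ|^α) / (2 Δ^α)

which is negative at t = Δ for α < 1 (anticorrelated increments) and decays
to zero from below as -(α - α²)(Δ/t)^(2-α)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Ensemble, Trajectory

__all__ = ["DAFCurve", "daf", "fbm_daf_exact", "fbm_daf_tail"]


@dataclass(frozen=True)
class DAFCurve:
    """Displacement autocorrelation at probe lag Δ on a grid of separations t."""

    lag: float  # Δ, ns
    t_grid: np.ndarray  # ns
    raw: np.ndarray  # nm²/ns²
    normalized: np.ndarray  # raw / raw at t=0
    averaging: str = "ensemble+origins"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "normalized", np.asarray(self.normalized, dtype=float))


def _daf_single(traj: Trajectory, k: int, t_steps: np.ndarray, time_origins: bool):
    """Per-axis increment covariance sums and counts at separations t_steps."""
    pos = traj.positions
    disp = pos[k:] - pos[:-k]  # increments of k steps, shape (n-k, d)
    sums = np.zeros(len(t_steps))
    counts = np.zeros(len(t_steps), dtype=int)
    for j, m in enumerate(t_steps):
        if time_origins:
            a = disp[: disp.shape[0] - m] if m else disp
            b = disp[m:]
            sums[j] = np.sum(a * b)
            counts[j] = a.shape[0] * traj.dim
        else:
            if m >= disp.shape[0]:
                raise ValueError("t + Δ exceeds trajectory duration")
            sums[j] = np.sum(disp[0] * disp[m])
            counts[j] = traj.dim
    return sums, counts


def daf(data: Ensemble | Trajectory, lag_ns: float, t_grid, time_origins: bool = True) -> DAFCurve:
    """Displacement autocorrelation function of a trajectory or ensemble.

    Averages over ensemble members and (by default) over shifted time
    origins; per-axis DAFs are averaged, each axis being an independent copy
    of the same process. ``t_grid`` must contain 0 so the normalization
    ``C_Δ(0)`` is computed from the same sample.
    """
    if lag_ns <= 0:
        raise ValueError("probe lag Δ must be positive")
    trajs = list(data) if isinstance(data, Ensemble) else [data]
    t0 = trajs[0]
    k = t0.lag_to_steps(lag_ns)
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if not np.isclose(t_grid[0], 0.0):
        t_grid = np.concatenate(([0.0], t_grid))
    t_steps = np.array([0 if np.isclose(t, 0) else t0.lag_to_steps(t) for t in t_grid])
    if (t_steps + k).max() > t0.n_steps - 1:
        raise ValueError("t + Δ exceeds trajectory duration")
    sums = np.zeros(len(t_steps))
    counts = np.zeros(len(t_steps), dtype=int)
    for traj in trajs:
        s, c = _daf_single(traj, k, t_steps, time_origins)
        sums += s
        counts += c
    raw = sums / counts / lag_ns**2
    if raw[0] <= 0:
        raise ValueError("C_Δ(0) must be positive to normalize")
    mode = "ensemble+origins" if time_origins else "ensemble"
    return DAFCurve(lag=lag_ns, t_grid=t_grid, raw=raw, normalized=raw / raw[0], averaging=mode)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must lie in (0, 2), got {alpha}")


def fbm_daf_exact(alpha: float, lag: float, t) -> np.ndarray:
    """Exact normalized DAF of free FBM: ((t+Δ)^α - 2t^α + |t-Δ|^α)/(2Δ^α)."""
    _check_alpha(alpha)
    if lag <= 0:
        raise ValueError("Δ must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    val = ((t + lag) ** alpha - 2.0 * t**alpha + np.abs(t - lag) ** alpha) / (2.0 * lag**alpha)
    return val if val.ndim else float(val)


def fbm_daf_tail(alpha: float, lag: float, t) -> np.ndarray:
    """Power-law tail of the FBM DAF: -(α - α²)(Δ/t)^(2-α)/2, valid for t > Δ."""
    _check_alpha(alpha)
    t = np.asarray(t, dtype=float)
    if np.any(t <= lag):
        raise ValueError("the tail form applies only for t > Δ")
    val = -(alpha - alpha**2) * (lag / t) ** (2.0 - alpha) / 2.0
    return val if val.ndim else float(val)
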