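"""Ergodicity diagnostics: scatter of TAMSDs across an ensemble.

The relative standard deviation (RSD) of TAMSDs at fixed lag Δ,

    R(t; Δ) = sqrt(⟨tamsd²⟩ - ⟨tamsd⟩²) / ⟨tamsd⟩,

measures how reproducible a single-trajectory TAMSD is at measurement time
``t``. For ergodic homogeneous processes (BM, subdiffusive FBM) it decays as
``t^(-1/2)``; a slower decay reveals diffusivity that persists over long
times (fluctuating diffusivity), even when the process is ergodic in the
infinite-time limit. Ensemble moments use the population convention
(divide by n), matching the angle-bracket averages; ``n`` is reported so
users can apply a small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Ensemble
from .msd import eamsd, tamsd_windowed

__all__ = ["RSDCurve", "rsd", "fit_rsd_exponent", "ergodicity_ratio", "default_t_grid"]


@dataclass(frozen=True)
class RSDCurve:
    """RSD of TAMSDs versus measurement time at fixed probe lag."""

    lag: float  # Δ, ns
    t_grid: np.ndarray  # ns
    values: np.ndarray  # dimensionless
    n_trajectories: int

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if t.size and t[0] <= self.lag:
            raise ValueError("every measurement time must exceed the lag")
        if np.any(v < 0):
            raise ValueError("RSD cannot be negative")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "values", v)


def default_t_grid(ensemble: Ensemble, lag_ns: float, per_decade: int = 8) -> np.ndarray:
    """Log-spaced measurement times from 10Δ to the trajectory duration."""
    t0 = ensemble[0]
    lo, hi = 10.0 * lag_ns, t0.duration
    if lo >= hi:
        raise ValueError("trajectory too short for the default t grid")
    n = max(3, int(np.log10(hi / lo) * per_decade) + 1)
    raw = np.logspace(np.log10(lo), np.log10(hi), n)
    # snap to the sampling grid and deduplicate
    steps = np.unique(np.round(raw / t0.dt).astype(int))
    return steps[steps * t0.dt > lag_ns] * t0.dt


def rsd(ensemble: Ensemble, lag_ns: float, t_grid) -> RSDCurve:
    """Relative standard deviation of TAMSDs across an ensemble.

    For each measurement time ``t`` the TAMSD of every member is evaluated
    with the data restricted to ``[0, t]``; the RSD is the population SD over
    members divided by the mean.
    """
    ensemble.require_homogeneous("RSD")
    if len(ensemble) < 2:
        raise ValueError("RSD needs at least 2 trajectories")
    t0 = ensemble[0]
    k = t0.lag_to_steps(lag_ns)
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid.max() > t0.duration + t0.dt:
        raise ValueError("t_grid exceeds trajectory duration")
    vals = np.empty(len(t_grid))
    for j, t in enumerate(t_grid):
        n_t = int(round(t / t0.dt))
        stop = n_t - k
        if stop < 1:
            raise ValueError(f"measurement time {t} ns leaves no window at lag {lag_ns} ns")
        per = np.array([tamsd_windowed(traj, k, 0, stop) for traj in ensemble])
        mean = per.mean()
        if mean <= 0:
            raise ValueError("zero mean TAMSD: RSD undefined")
        vals[j] = np.sqrt(np.clip(np.mean(per**2) - mean**2, 0.0, None)) / mean
    return RSDCurve(lag=lag_ns, t_grid=t_grid, values=vals, n_trajectories=len(ensemble))


def fit_rsd_exponent(curve: RSDCurve, window: tuple[float, float] | None = None):
    """Least-squares log-log slope of R versus t; returns (slope, stderr)."""
    t, v = curve.t_grid, curve.values
    if window is not None:
        lo, hi = window
        mask = (t >= lo * (1 - 1e-9)) & (t <= hi * (1 + 1e-9))
        t, v = t[mask], v[mask]
    if t.size < 3:
        raise ValueError("need at least 3 points in the fit window")
    if np.any(v <= 0):
        raise ValueError("nonpositive RSD values in window: cannot take log")
    (slope, _), cov = np.polyfit(np.log(t), np.log(v), 1, cov=True)
    return float(slope), float(np.sqrt(cov[0, 0]))


def ergodicity_ratio(ensemble: Ensemble, lags, t_ns: float | None = None) -> np.ndarray:
    """Per-lag ratio of the ensemble-mean TAMSD to the EAMSD.

    Ratios near 1 at every lag indicate that time and ensemble averages
    agree (ergodic behavior at the achieved measurement time).
    """
    ensemble.require_homogeneous("ergodicity ratio")
    t0 = ensemble[0]
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    if t_ns is None:
        t_ns = t0.duration + t0.dt
    n_t = int(round(t_ns / t0.dt))
    mean_tamsd = np.empty(len(lags))
    for i, lag in enumerate(lags):
        k = t0.lag_to_steps(lag)
        stop = n_t - k
        if stop < 1:
            raise ValueError(f"lag {lag} ns leaves no window at measurement time {t_ns} ns")
        mean_tamsd[i] = np.mean([tamsd_windowed(traj, k, 0, stop) for traj in ensemble])
    ea = eamsd(ensemble, lags).values
    if np.any(ea <= 0):
        raise ValueError("zero EAMSD: ratio undefined")
    return mean_tamsd / ea
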