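"""Time- and ensemble-averaged mean squared displacement statistics.

The time-averaged MSD (TAMSD) of a trajectory observed for a measurement
time ``t`` at lag ``Δ`` is

    tamsd(Δ; t) = 1/(t - Δ) ∫₀^{t-Δ} |r(t' + Δ) - r(t')|² dt'

discretized as the mean over all overlapping start indices on the sampling
grid. For normal diffusion ``tamsd ~ 2 d D Δ``; subdiffusion appears as
``tamsd ∝ Δ^α`` with ``α < 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Ensemble, Trajectory
from .units import d_nm2ns_to_um2s

__all__ = [
    "MSDCurve",
    "tamsd",
    "eamsd",
    "aging_curve",
    "fit_exponent",
    "diffusion_coefficient",
    "default_lag_grid",
]


@dataclass(frozen=True)
class MSDCurve:
    """A lag-indexed MSD curve with its provenance metadata."""

    lags: np.ndarray  # ns, strictly increasing
    values: np.ndarray  # nm²
    measurement_time: float  # ns
    n_trajectories: int = 1
    kind: str = "tamsd"

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.ndim != 1 or values.shape != lags.shape:
            raise ValueError("lags and values must be 1-D arrays of equal length")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if lags.size and lags[-1] >= self.measurement_time:
            raise ValueError("maximum lag must be below the measurement time")
        if np.any(values < 0):
            raise ValueError("MSD values cannot be negative")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)

    def value_at(self, lag_ns: float) -> float:
        idx = np.flatnonzero(np.isclose(self.lags, lag_ns, rtol=1e-9))
        if idx.size == 0:
            raise ValueError(f"lag {lag_ns} ns is not on the curve grid")
        return float(self.values[idx[0]])


def default_lag_grid(traj: Trajectory, per_decade: int = 16, max_fraction: float = 0.25) -> np.ndarray:
    """Log-spaced subset of integer step multiples, ~``per_decade`` per decade."""
    k_max = max(1, int((traj.n_steps - 2) * max_fraction))
    if k_max < 2:
        return np.array([traj.dt])
    raw = np.logspace(0, np.log10(k_max), int(np.log10(k_max) * per_decade) + 1)
    ks = np.unique(np.round(raw).astype(int))
    return ks[ks >= 1] * traj.dt


def _lag_steps(traj: Trajectory, lags) -> np.ndarray:
    return np.array([traj.lag_to_steps(l) for l in np.atleast_1d(np.asarray(lags, dtype=float))])


def tamsd(traj: Trajectory, lags) -> MSDCurve:
    """Time-averaged MSD of one trajectory at the requested lags (ns).

    Lags must be positive multiples of ``dt`` (no interpolation) and leave at
    least one displacement window inside the trajectory.
    """
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    ks = _lag_steps(traj, lags)
    if ks.max() > traj.n_steps - 2:
        raise ValueError(
            f"maximum lag {lags.max()} ns exceeds (length-2)*dt = {(traj.n_steps - 2) * traj.dt} ns"
        )
    pos = traj.positions
    vals = np.empty(len(ks))
    for i, k in enumerate(ks):
        disp = pos[k:] - pos[:-k]
        vals[i] = np.mean(np.sum(disp * disp, axis=1))
    return MSDCurve(
        lags=lags, values=vals, measurement_time=traj.duration + traj.dt, n_trajectories=1
    )


def tamsd_windowed(traj: Trajectory, lag_steps: int, start: int, stop: int) -> float:
    """TAMSD at integer lag over displacement windows starting in [start, stop).

    Helper shared with the short-time diffusivity estimator; ``stop`` is the
    exclusive bound on the displacement start index.
    """
    if stop <= start:
        raise ValueError("empty TAMSD window")
    pos = traj.positions
    disp = pos[start + lag_steps : stop + lag_steps] - pos[start:stop]
    return float(np.mean(np.sum(disp * disp, axis=1)))


def eamsd(ensemble: Ensemble, lags) -> MSDCurve:
    """Ensemble-averaged MSD: squared displacement from each member's origin."""
    ensemble.require_homogeneous("EAMSD")
    t0 = ensemble[0]
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    ks = _lag_steps(t0, lags)
    if ks.max() > t0.n_steps - 1:
        raise ValueError("maximum lag exceeds trajectory duration")
    origins = np.stack([t.positions[0] for t in ensemble])
    vals = np.empty(len(ks))
    for i, k in enumerate(ks):
        disp = np.stack([t.positions[k] for t in ensemble]) - origins
        vals[i] = np.mean(np.sum(disp * disp, axis=1))
    return MSDCurve(
        lags=lags,
        values=vals,
        measurement_time=t0.duration + t0.dt,
        n_trajectories=len(ensemble),
        kind="eamsd",
    )


def aging_curve(ensemble: Ensemble, lag_ns: float, t_grid) -> np.ndarray:
    """Ensemble mean of the TAMSD at fixed lag, as a function of measurement time.

    A stationary process shows no aging: the curve is flat in ``t``.
    """
    ensemble.require_homogeneous("aging curve")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    t0 = ensemble[0]
    if lag_ns >= t_grid.min():
        raise ValueError("lag must be below every measurement time in t_grid")
    if t_grid.max() > t0.duration + t0.dt:
        raise ValueError("t_grid exceeds trajectory duration")
    k = t0.lag_to_steps(lag_ns)
    out = np.empty(len(t_grid))
    for j, t in enumerate(t_grid):
        n_t = int(round(t / t0.dt))  # samples available within measurement time t
        stop = n_t - k
        out[j] = np.mean([tamsd_windowed(traj, k, 0, stop) for traj in ensemble])
    return out


def fit_exponent(curve: MSDCurve, fit_window: tuple[float, float] | None = None):
    """Least-squares log-log slope of an MSD curve over a lag window.

    Returns ``(alpha, stderr)``. The window is ``(lag_min, lag_max)`` in ns,
    inclusive; default uses the whole curve.
    """
    lags, vals = curve.lags, curve.values
    if fit_window is not None:
        lo, hi = fit_window
        mask = (lags >= lo * (1 - 1e-9)) & (lags <= hi * (1 + 1e-9))
        lags, vals = lags[mask], vals[mask]
    if lags.size < 3:
        raise ValueError("need at least 3 points in the fit window")
    if np.any(vals <= 0):
        raise ValueError("nonpositive MSD values in fit window: cannot take log")
    x, y = np.log(lags), np.log(vals)
    (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    return float(slope), float(np.sqrt(cov[0, 0]))


def diffusion_coefficient(curve: MSDCurve, lag_ns: float, dim: int) -> float:
    """Diffusion coefficient ``D = msd(Δ)/(2 d Δ)`` in μm²/s."""
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    val = curve.value_at(lag_ns)
    return d_nm2ns_to_um2s(val / (2.0 * dim * lag_ns))
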