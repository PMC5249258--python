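"""Core containers for single-particle trajectory analysis.

All positions are stored in nanometres and times in nanoseconds; diffusion
coefficients are reported in μm²/s (1 nm²/ns = 10³ μm²/s, see
:mod:`fluctodiff.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "Ensemble",
    "StateSeries",
    "CovariateSeries",
    "remove_linear_drift",
]


def _as_float_array(a, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))
        raise ValueError(f"{name} contains non-finite values (first at index {tuple(bad[0])})")
    return arr


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled trajectory of one tracked particle.

    Parameters
    ----------
    times
        Sample times in ns, uniformly spaced with positive step ``dt``.
    positions
        Array of shape ``(n, d)`` with ``d`` in {1, 2, 3}, coordinates in nm.
    traj_id
        Optional label carried through to serialized output.
    """

    times: np.ndarray
    positions: np.ndarray
    traj_id: str = ""

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times", 1)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim == 1:
            pos = pos[:, None]
        pos = _as_float_array(pos, "positions", 2)
        if times.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if pos.shape[0] != times.shape[0]:
            raise ValueError(
                f"times ({times.shape[0]}) and positions ({pos.shape[0]}) length mismatch"
            )
        if pos.shape[1] not in (1, 2, 3):
            raise ValueError(f"dimension must be 1, 2 or 3, got {pos.shape[1]}")
        steps = np.diff(times)
        dt = steps[0]
        if dt <= 0:
            raise ValueError("time step must be positive")
        if not np.allclose(steps, dt, rtol=1e-9, atol=0.0):
            raise ValueError("sampling must be uniform (non-constant dt detected)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", pos)

    @property
    def dt(self) -> float:
        """Sampling interval in ns."""
        return float(self.times[1] - self.times[0])

    @property
    def n_steps(self) -> int:
        return int(self.times.shape[0])

    @property
    def dim(self) -> int:
        return int(self.positions.shape[1])

    @property
    def duration(self) -> float:
        """Total observation time in ns."""
        return float(self.times[-1] - self.times[0])

    def lag_to_steps(self, lag_ns: float) -> int:
        """Convert a lag in ns to an integer number of sampling steps.

        Rejects lags that do not fall on the sampling grid — no interpolation.
        """
        k = lag_ns / self.dt
        k_int = int(round(k))
        if k_int < 1 or not np.isclose(k, k_int, rtol=1e-6, atol=1e-9):
            raise ValueError(f"lag {lag_ns} ns is not a positive multiple of dt={self.dt} ns")
        return k_int


@dataclass(frozen=True)
class Ensemble:
    """A collection of trajectories sharing sampling parameters.

    Ensemble statistics (ensemble-averaged MSD, RSD, propagators) require all
    members to share ``dt``, length and dimension; per-trajectory statistics
    do not, which is why homogeneity is checked lazily via
    :meth:`require_homogeneous`.
    """

    trajectories: tuple[Trajectory, ...]

    def __post_init__(self) -> None:
        trajs = tuple(self.trajectories)
        if len(trajs) == 0:
            raise ValueError("ensemble must contain at least one trajectory")
        object.__setattr__(self, "trajectories", trajs)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Ensemble(self.trajectories[i])
        return self.trajectories[i]

    @property
    def is_homogeneous(self) -> bool:
        t0 = self.trajectories[0]
        return all(
            np.isclose(t.dt, t0.dt, rtol=1e-9)
            and t.n_steps == t0.n_steps
            and t.dim == t0.dim
            for t in self.trajectories
        )

    def require_homogeneous(self, context: str = "ensemble statistic") -> None:
        if not self.is_homogeneous:
            t0 = self.trajectories[0]
            offending = [
                t.traj_id or str(i)
                for i, t in enumerate(self.trajectories)
                if not (
                    np.isclose(t.dt, t0.dt, rtol=1e-9)
                    and t.n_steps == t0.n_steps
                    and t.dim == t0.dim
                )
            ]
            raise ValueError(
                f"{context} requires shared dt/length/dimension; "
                f"mismatching members: {offending}"
            )

    @property
    def dt(self) -> float:
        self.require_homogeneous("dt access")
        return self.trajectories[0].dt

    @property
    def dim(self) -> int:
        self.require_homogeneous("dim access")
        return self.trajectories[0].dim


@dataclass(frozen=True)
class StateSeries:
    """Realized two-state (fast/slow) path of a fluctuating-diffusivity model.

    ``switch_times`` are the instants (ns) at which the state changes;
    ``labels`` gives the state occupied in each inter-switch interval,
    starting at time 0, strictly alternating between ``"F"`` and ``"S"``.
    ``t_end`` closes the final sojourn.
    """

    switch_times: np.ndarray
    labels: tuple[str, ...]
    t_end: float

    def __post_init__(self) -> None:
        st = _as_float_array(np.atleast_1d(self.switch_times), "switch_times", 1)
        labels = tuple(self.labels)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("switch_times must be strictly increasing")
        if len(labels) != st.size + 1:
            raise ValueError("need exactly one label per sojourn (len(switch_times)+1)")
        for a, b in zip(labels, labels[1:]):
            if a == b or a not in ("F", "S") or b not in ("F", "S"):
                raise ValueError("labels must strictly alternate between 'F' and 'S'")
        if st.size and st[-1] >= self.t_end:
            raise ValueError("switch_times must lie inside [0, t_end)")
        object.__setattr__(self, "switch_times", st)
        object.__setattr__(self, "labels", labels)

    @property
    def sojourns(self) -> np.ndarray:
        """Durations (ns) of all sojourns, including the censored last one."""
        edges = np.concatenate(([0.0], self.switch_times, [self.t_end]))
        return np.diff(edges)

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """Label ('F'/'S') occupied at each query time."""
        idx = np.searchsorted(self.switch_times, np.asarray(times, dtype=float), side="right")
        lab = np.array(self.labels)
        return lab[idx]

    def interval_index(self, times: np.ndarray) -> np.ndarray:
        """Index of the sojourn interval containing each query time."""
        return np.searchsorted(self.switch_times, np.asarray(times, dtype=float), side="right")


@dataclass(frozen=True)
class CovariateSeries:
    """A nonnegative integer covariate (e.g. bound-lipid count) on a trajectory grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times", 1)
        values = np.asarray(self.values)
        if values.shape != times.shape:
            raise ValueError("times and values must have equal length")
        if np.any(values < 0):
            raise ValueError("covariate values must be nonnegative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", np.asarray(values, dtype=float))

    def mean_over(self, t_lo: float, t_hi: float) -> float:
        mask = (self.times >= t_lo) & (self.times < t_hi)
        if not np.any(mask):
            raise ValueError(f"no covariate samples in [{t_lo}, {t_hi}) ns")
        return float(np.mean(self.values[mask]))


def remove_linear_drift(traj: Trajectory) -> Trajectory:
    """Subtract the least-squares linear drift from each coordinate.

    Generic stand-in for reference-frame corrections applied upstream of the
    statistics (e.g. removing collective motion of the medium).
    """
    t = traj.times - traj.times[0]
    A = np.vander(t, 2)
    coef, *_ = np.linalg.lstsq(A, traj.positions, rcond=None)
    detrended = traj.positions - A @ coef + np.mean(traj.positions, axis=0, keepdims=True)
    return Trajectory(times=traj.times, positions=detrended, traj_id=traj.traj_id)
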