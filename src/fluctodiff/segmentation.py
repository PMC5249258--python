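"""Short-time diffusivity estimation by renewal-time segmentation.

A long trajectory whose diffusivity switches between states is segmented in
three stages:

1. a *temporal diffusion coefficient* ``D(t; Δ, T)`` — the TAMSD at lag Δ
   restricted to the sliding window ``[t, t + T - Δ]``, divided by ``2 d Δ``;
2. *renewal times*: instants where ``D(t)`` strictly crosses its
   whole-trajectory mean ``D_a``; a crossing is confirmed as a state switch
   when the occupation fractions over the forward confirmation window
   ``[t_i, t_i + T_c]``,

       ρ_F(t_i) = fraction of the window with D > D_a,
       ρ_S(t_i) = fraction with D < D_a,

   favor the state the crossing enters (ρ_F > ρ_S for S→F, mirrored for
   F→S); confirmed renewals must alternate direction;
3. a *short-time diffusion coefficient* per segment ``[t_i, t_{i+1}]``: the
   windowed TAMSD at a much shorter lag, divided by ``2 d Δ``.

Defaults follow the scales used for membrane-protein trajectories sampled
at 0.1 ns: Δ = 0.1 μs and T = 1 μs for the
temporal series, T_c = 10 ns for confirmation, Δ = 0.1 ns for the
per-segment short-time estimate.

The sojourn-time distribution of the recovered segments is fitted by maximum
likelihood of the exponentially cut-off power law
``rho(tau) ∝ tau**(-1-gamma) exp(-tau/tau_c)`` truncated at ``tau_0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .core import CovariateSeries, Trajectory
from .units import d_nm2ns_to_um2s

__all__ = [
    "TemporalDiffusivitySeries",
    "RenewalDetection",
    "SegmentationResult",
    "SojournFit",
    "temporal_diffusivity",
    "detect_renewal_times",
    "segment_diffusivity",
    "segment_trajectory",
    "correlate_with_covariate",
    "fit_sojourn_distribution",
    "sojourn_log_normalizer",
]

DEFAULT_LAG_NS = 100.0  # Δ = 0.1 μs
DEFAULT_WINDOW_NS = 1000.0  # T = 1 μs
DEFAULT_TC_NS = 10.0  # confirmation window T_c
DEFAULT_SHORT_LAG_NS = 0.1  # per-segment short lag


@dataclass(frozen=True)
class TemporalDiffusivitySeries:
    """Windowed diffusion coefficient D(t; Δ, T) on a time grid."""

    t_grid: np.ndarray  # ns, window start times
    values: np.ndarray  # μm²/s
    lag: float  # Δ, ns
    window: float  # T, ns

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t_grid and values must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("diffusivities cannot be negative")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "values", v)

    @property
    def d_a(self) -> float:
        """Whole-trajectory mean of the temporal diffusivity (μm²/s)."""
        return float(np.mean(self.values))


@dataclass(frozen=True)
class RenewalDetection:
    """Candidate and confirmed mean-crossings of the temporal diffusivity."""

    candidate_times: np.ndarray  # ns
    confirmed_times: np.ndarray  # ns
    directions: tuple[str, ...]  # 'SF' or 'FS' per confirmed renewal
    truncated: tuple[bool, ...]  # confirmation window ran past the series end
    d_a: float
    t_c: float


@dataclass(frozen=True)
class SegmentationResult:
    """Per-segment short-time diffusivities between renewal times."""

    renewal_times: np.ndarray  # ns, interior boundaries
    bounds: np.ndarray  # ns, len = n_segments + 1, includes 0 and duration
    labels: tuple[str, ...]  # 'F'/'S' per segment (D above/below D_a)
    segment_d: np.ndarray  # μm²/s per segment
    short_lag: float  # ns
    t_c: float
    d_a: float
    n_merged: int = 0
    covariate_means: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.labels)

    @property
    def segment_durations(self) -> np.ndarray:
        return np.diff(self.bounds)


def temporal_diffusivity(
    traj: Trajectory,
    lag_ns: float = DEFAULT_LAG_NS,
    window_ns: float = DEFAULT_WINDOW_NS,
    stride: int = 1,
) -> TemporalDiffusivitySeries:
    """Temporal diffusion coefficient D(t; Δ, T) of one trajectory.

    ``D(t) = [TAMSD over window [t, t + T - Δ] at lag Δ] / (2 d Δ)``,
    evaluated at window starts spaced ``stride`` sampling steps apart. The
    windowed average runs over all displacement start times in
    ``[t, t + T - Δ]``, implemented with a cumulative sum (O(N) overall).
    """
    m = traj.lag_to_steps(lag_ns)
    if window_ns <= lag_ns:
        raise ValueError(f"window T={window_ns} ns must exceed lag Δ={lag_ns} ns")
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    w = int(round((window_ns - lag_ns) / traj.dt))
    if not np.isclose(w * traj.dt, window_ns - lag_ns, rtol=1e-6):
        raise ValueError("T - Δ must be a multiple of dt")
    n = traj.n_steps
    if w + m > n - 1:
        raise ValueError(f"window T={window_ns} ns exceeds trajectory duration")
    sq = np.sum((traj.positions[m:] - traj.positions[:-m]) ** 2, axis=1)
    c = np.concatenate(([0.0], np.cumsum(sq)))
    # displacement start indices j .. j+w inclusive lie in the window
    starts = np.arange(0, n - 1 - m - w + 1, stride)
    means = (c[starts + w + 1] - c[starts]) / (w + 1)
    d_vals = d_nm2ns_to_um2s(means / (2.0 * traj.dim * lag_ns))
    return TemporalDiffusivitySeries(
        t_grid=starts * traj.dt, values=d_vals, lag=lag_ns, window=window_ns
    )


def detect_renewal_times(
    series: TemporalDiffusivitySeries, t_c: float = DEFAULT_TC_NS
) -> RenewalDetection:
    """Find and confirm mean-crossings of the temporal diffusivity.

    Candidates are strict sign changes of ``D - D_a`` between consecutive
    grid points; the renewal time is the earlier grid point. Candidates are
    processed left to right, skipping any that fall inside an already
    confirmed renewal's confirmation window, and confirmations that fail to
    alternate direction are dropped (the first is kept).
    """
    if t_c <= 0:
        raise ValueError("T_c must be positive")
    t, v = series.t_grid, series.values
    if t.size < 2:
        raise ValueError("temporal diffusivity series is too short")
    d_a = series.d_a
    dev = v - d_a
    sign = np.sign(dev)
    cross = np.flatnonzero((sign[:-1] != 0) & (sign[1:] != 0) & (sign[:-1] != sign[1:]))
    candidate_times = t[cross]

    confirmed: list[float] = []
    directions: list[str] = []
    truncated: list[bool] = []
    for idx in cross:
        ti = t[idx]
        if confirmed and ti < confirmed[-1] + t_c:
            continue  # inside the previous renewal's confirmation window
        direction = "SF" if sign[idx] < 0 else "FS"
        in_win = (t >= ti) & (t < ti + t_c)
        was_truncated = bool(t[-1] < ti + t_c - 1e-9)
        frac_f = np.mean(v[in_win] > d_a)
        frac_s = np.mean(v[in_win] < d_a)
        ok = frac_f > frac_s if direction == "SF" else frac_s > frac_f
        if not ok:
            continue
        if directions and directions[-1] == direction:
            continue  # non-alternating confirmation: keep the first
        confirmed.append(float(ti))
        directions.append(direction)
        truncated.append(was_truncated)
    return RenewalDetection(
        candidate_times=candidate_times,
        confirmed_times=np.array(confirmed),
        directions=tuple(directions),
        truncated=tuple(truncated),
        d_a=d_a,
        t_c=t_c,
    )


def segment_diffusivity(
    traj: Trajectory,
    renewal_times,
    short_lag_ns: float = DEFAULT_SHORT_LAG_NS,
    d_a: float | None = None,
    t_c: float = DEFAULT_TC_NS,
    covariate: CovariateSeries | None = None,
) -> SegmentationResult:
    """Short-time diffusion coefficient per inter-renewal segment.

    Each segment ``[t_i, t_{i+1}]`` gets the windowed TAMSD at
    ``short_lag_ns`` divided by ``2 d Δ``. Segments shorter than twice the
    short lag (including renewals falling on the trajectory boundaries) are
    merged into their left neighbor and counted in ``n_merged``. Each
    segment is labeled fast ('F') or slow ('S') by comparing its diffusivity
    with the whole-trajectory mean ``d_a`` (default: the duration-weighted
    mean of the segment values).
    """
    m = traj.lag_to_steps(short_lag_ns)
    renewal_times = np.sort(np.atleast_1d(np.asarray(renewal_times, dtype=float)))
    if renewal_times.size and (
        renewal_times[0] < 0 or renewal_times[-1] > traj.duration
    ):
        raise ValueError("renewal times must lie inside [0, duration]")
    bounds_idx = [0]
    n_merged = 0
    for rt in renewal_times:
        idx = int(round(rt / traj.dt))
        if idx - bounds_idx[-1] < 2 * m:
            n_merged += 1  # segment too short to estimate: merge left
            continue
        bounds_idx.append(idx)
    last = traj.n_steps - 1
    if last - bounds_idx[-1] < 2 * m:
        if len(bounds_idx) > 1:
            bounds_idx.pop()
            n_merged += 1
        else:
            raise ValueError("trajectory too short for the requested short lag")
    bounds_idx.append(last)

    seg_d = np.empty(len(bounds_idx) - 1)
    pos = traj.positions
    for i, (a, b) in enumerate(zip(bounds_idx[:-1], bounds_idx[1:])):
        disp = pos[a + m : b + 1] - pos[a : b + 1 - m]
        seg_d[i] = d_nm2ns_to_um2s(
            np.mean(np.sum(disp * disp, axis=1)) / (2.0 * traj.dim * short_lag_ns)
        )
    bounds = np.array(bounds_idx) * traj.dt

    durations = np.diff(bounds)
    if d_a is None:
        d_a = float(np.sum(seg_d * durations) / durations.sum())
    labels = tuple("F" if d > d_a else "S" for d in seg_d)

    cov_means = None
    if covariate is not None:
        if covariate.times[0] > bounds[0] or covariate.times[-1] < bounds[-1] - 1e-9:
            raise ValueError("covariate does not cover the trajectory span")
        cov_means = np.array(
            [covariate.mean_over(a, b if b < bounds[-1] else b + 1e-9) for a, b in zip(bounds[:-1], bounds[1:])]
        )
    return SegmentationResult(
        renewal_times=bounds[1:-1],
        bounds=bounds,
        labels=labels,
        segment_d=seg_d,
        short_lag=short_lag_ns,
        t_c=t_c,
        d_a=float(d_a),
        n_merged=n_merged,
        covariate_means=cov_means,
    )


def segment_trajectory(
    traj: Trajectory,
    lag_ns: float = DEFAULT_LAG_NS,
    window_ns: float = DEFAULT_WINDOW_NS,
    t_c: float = DEFAULT_TC_NS,
    short_lag_ns: float = DEFAULT_SHORT_LAG_NS,
    stride: int = 1,
    covariate: CovariateSeries | None = None,
) -> tuple[TemporalDiffusivitySeries, RenewalDetection, SegmentationResult]:
    """Run the full pipeline: temporal D(t) → renewal detection → segment D."""
    series = temporal_diffusivity(traj, lag_ns, window_ns, stride)
    detection = detect_renewal_times(series, t_c)
    result = segment_diffusivity(
        traj,
        detection.confirmed_times,
        short_lag_ns=short_lag_ns,
        d_a=detection.d_a,
        t_c=t_c,
        covariate=covariate,
    )
    return series, detection, result


def correlate_with_covariate(
    result: SegmentationResult, covariate: CovariateSeries | None = None
):
    """Pearson correlation between segment diffusivity and covariate mean.

    Returns ``(r, n_segments)``. Uses the covariate means already attached to
    the result, or computes them from ``covariate``.
    """
    if result.covariate_means is not None:
        means = result.covariate_means
    elif covariate is not None:
        means = np.array(
            [covariate.mean_over(a, b) for a, b in zip(result.bounds[:-1], result.bounds[1:])]
        )
    else:
        raise ValueError("no covariate provided")
    if result.n_segments < 3:
        raise ValueError(f"need at least 3 segments, got {result.n_segments}")
    r = stats.pearsonr(result.segment_d, means).statistic
    return float(r), result.n_segments


# ---------------------------------------------------------------------------
# sojourn-time distribution fitting


def _upper_gamma(a: float, x: float) -> float:
    """Upper incomplete gamma Γ(a, x) for any real shape, x > 0.

    For a ≤ 0 the library routine does not apply; the recurrence
    Γ(a, x) = (Γ(a + 1, x) - x^a e^(-x)) / a walks the shape up until it is
    positive (Γ(0, x) is the exponential integral E1).
    """
    if a > 0:
        return float(special.gammaincc(a, x) * special.gamma(a))
    if a == 0.0:
        return float(special.exp1(x))
    return (_upper_gamma(a + 1.0, x) - x**a * np.exp(-x)) / a


def sojourn_log_normalizer(gamma: float, tau_c: float, tau_0: float) -> float:
    """log ∫_{tau_0}^∞ τ^(-1-γ) exp(-τ/τ_c) dτ = log[τ_c^(-γ) Γ(-γ, τ_0/τ_c)]."""
    if gamma <= 0 or gamma >= 1.999999:
        raise ValueError("gamma must lie in (0, 2)")
    x = tau_0 / tau_c
    g_upper = _upper_gamma(-gamma, x)
    if not np.isfinite(g_upper) or g_upper <= 0:
        raise FloatingPointError("incomplete gamma recurrence lost precision")
    return float(-gamma * np.log(tau_c) + np.log(g_upper))


@dataclass(frozen=True)
class SojournFit:
    """Maximum-likelihood fit of the exponentially cut-off power law."""

    gamma: float
    tau_c: float
    se_gamma: float
    se_tau_c: float
    loglik: float
    n: int
    tau_0: float
    converged: bool
    message: str = ""


def _sojourn_nll(theta, sum_log, sum_tau, n, tau_0):
    gamma, log_tau_c = theta
    tau_c = np.exp(log_tau_c)
    try:
        log_z = sojourn_log_normalizer(gamma, tau_c, tau_0)
    except (ValueError, FloatingPointError):
        return 1e300
    return n * log_z + (1.0 + gamma) * sum_log + sum_tau / tau_c


def fit_sojourn_distribution(sojourns, tau_0: float, min_n: int = 100) -> SojournFit:
    """Fit ``rho(tau) ∝ tau^(-1-γ) exp(-τ/τ_c)`` on ``[tau_0, ∞)`` by MLE.

    Optimizes ``(γ, log τ_c)`` with bounded Nelder–Mead from the starting
    point γ = 0.5, τ_c = max(sojourns) (derivative-free: near the γ → 0
    boundary the normalizer's numerical gradient is unreliable); standard
    errors come from the observed information (finite-difference Hessian of
    the negative log-likelihood). Non-convergence raises with the optimizer
    diagnostics.
    """
    tau = np.asarray(sojourns, dtype=float)
    if tau.size < min_n:
        raise ValueError(f"need at least {min_n} sojourns, got {tau.size}")
    if tau_0 <= 0 or np.any(tau < tau_0):
        raise ValueError("all sojourns must be ≥ tau_0 > 0")
    sum_log, sum_tau, n = np.sum(np.log(tau)), np.sum(tau), tau.size
    x0 = np.array([0.5, np.log(tau.max())])
    bounds = [(1e-6, 1.99), (np.log(tau_0), np.log(tau.max()) + 15.0)]
    res = optimize.minimize(
        _sojourn_nll,
        x0,
        args=(sum_log, sum_tau, n, tau_0),
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    if not res.success:
        raise RuntimeError(
            f"sojourn-distribution MLE did not converge: {res.message} "
            f"(last point γ={res.x[0]:.4f}, τ_c={np.exp(res.x[1]):.4g}, nll={res.fun:.6g})"
        )
    gamma_hat, log_tc_hat = res.x
    tau_c_hat = float(np.exp(log_tc_hat))

    # observed information from a central-difference Hessian
    h = np.array([1e-4, 1e-4])
    H = np.empty((2, 2))
    f0 = _sojourn_nll(res.x, sum_log, sum_tau, n, tau_0)
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            H[i, j] = (
                _sojourn_nll(res.x + ei + ej, sum_log, sum_tau, n, tau_0)
                - _sojourn_nll(res.x + ei - ej, sum_log, sum_tau, n, tau_0)
                - _sojourn_nll(res.x - ei + ej, sum_log, sum_tau, n, tau_0)
                + _sojourn_nll(res.x - ei - ej, sum_log, sum_tau, n, tau_0)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se_gamma = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_log_tc = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_gamma, se_log_tc = np.nan, np.nan
    return SojournFit(
        gamma=float(gamma_hat),
        tau_c=tau_c_hat,
        se_gamma=se_gamma,
        se_tau_c=tau_c_hat * se_log_tc,  # delta method on log τ_c
        loglik=-float(f0),
        n=n,
        tau_0=float(tau_0),
        converged=bool(res.success),
        message=str(res.message),
    )
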