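"""Synthetic trajectory generators.

Three generative models of lateral diffusion are provided:

* ordinary Brownian motion (BM) — the ergodic reference;
* fractional Brownian motion (FBM) — Gaussian, stationary, power-law
  correlated increments, MSD per axis ``k_alpha * t**alpha``; subdiffusion
  (``alpha < 1``) gives the anticorrelated increments characteristic of
  lipid-mediated motion at sub-crossover lag times;
* an overdamped Langevin equation with fluctuating diffusivity (LEFD) —
  ``dx = sqrt(2 D(t)) dW`` with ``D(t)`` switching dichotomously between a
  fast and a slow value, sojourn times drawn from an exponentially cut-off
  power law ``rho(tau) ∝ tau**(-1-gamma) * exp(-tau/tau_c)``.

A piecewise-constant bound-lipid covariate generator emulates the count of
lipids bound to the tracked protein, anti-correlated with diffusivity, so the
state–covariate correlation stage can be exercised without molecular
dynamics data.

All generators are pure functions of their parameters and seed; with the
same seed the output is bitwise identical. Master seeds spawn per-trajectory
child seeds through :func:`numpy.random.SeedSequence.spawn`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, toeplitz

from .core import CovariateSeries, StateSeries, Trajectory
from .units import d_um2s_to_nm2ns

__all__ = [
    "FBMParams",
    "LEFDParams",
    "generate_bm",
    "generate_fbm",
    "sample_sojourns",
    "generate_lefd",
    "generate_bound_count",
    "fbm_increment_autocovariance",
    "bm_ensemble",
    "fbm_ensemble",
    "lefd_ensemble",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seeds from one master seed."""
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)


@dataclass(frozen=True)
class FBMParams:
    """Fractional Brownian motion parameters.

    ``alpha`` is the anomalous MSD exponent (= 2H); ``k_alpha`` the
    generalized diffusion scale in nm²/ns^alpha, normalized so that the
    per-axis MSD is ``k_alpha * t**alpha`` (for ``alpha = 1`` this is BM with
    ``k_alpha = 2 D``).
    """

    alpha: float
    k_alpha: float
    dim: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 2.0:
            raise ValueError(f"alpha must lie in (0, 2), got {self.alpha}")
        if self.k_alpha <= 0:
            raise ValueError("k_alpha must be positive")
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")


@dataclass(frozen=True)
class LEFDParams:
    """Two-state fluctuating-diffusivity model parameters.

    Diffusion coefficients in μm²/s; time scales in ns. Sojourn times of both
    states follow ``rho(tau) ∝ tau**(-1-gamma) * exp(-tau/tau_c)`` on
    ``[tau_0, inf)``; set ``gamma_slow``/``tau_c_slow`` to give the slow
    state its own sojourn law.
    """

    d_fast: float
    d_slow: float
    gamma: float
    tau_c: float
    tau_0: float
    dim: int = 2
    gamma_slow: float | None = None
    tau_c_slow: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.d_slow < self.d_fast:
            raise ValueError("need 0 < d_slow < d_fast")
        for g in (self.gamma, self.gamma_slow):
            if g is not None and not 0.0 < g <= 1.0:
                raise ValueError("gamma must lie in (0, 1]")
        if not self.tau_c > self.tau_0 > 0.0:
            raise ValueError("need tau_c > tau_0 > 0")
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")


def _check_grid(n_steps: int, dt: float) -> None:
    if n_steps < 2:
        raise ValueError(f"n_steps must be at least 2, got {n_steps}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")


def generate_bm(
    D: float, n_steps: int, dt: float, dim: int = 2, seed=None, traj_id: str = ""
) -> Trajectory:
    """Simulate ordinary Brownian motion.

    Parameters
    ----------
    D
        Diffusion coefficient in μm²/s.
    n_steps
        Number of recorded positions (including the origin).
    dt
        Sampling interval in ns.
    """
    if D < 0:
        raise ValueError(f"diffusion coefficient must be nonnegative, got {D}")
    _check_grid(n_steps, dt)
    rng = _rng(seed)
    d_nm = d_um2s_to_nm2ns(D)
    sigma = np.sqrt(2.0 * d_nm * dt)
    incr = rng.normal(0.0, 1.0, size=(n_steps - 1, dim)) * sigma
    pos = np.vstack([np.zeros((1, dim)), np.cumsum(incr, axis=0)])
    times = np.arange(n_steps) * dt
    return Trajectory(times=times, positions=pos, traj_id=traj_id)


def fbm_increment_autocovariance(params: FBMParams, dt: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-step FBM increments at integer lags (nm²).

    ``cov(k) = k_alpha * dt**alpha * (|k+1|**a - 2|k|**a + |k-1|**a) / 2``.
    """
    k = np.abs(np.asarray(lags, dtype=float))
    a = params.alpha
    return (
        0.5
        * params.k_alpha
        * dt**a
        * (np.abs(k + 1) ** a - 2.0 * k**a + np.abs(k - 1) ** a)
    )


def _fgn_davies_harte(acov: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary Gaussian sample via circulant embedding.

    Returns ``n`` fractional Gaussian noise values with autocovariance
    ``acov[0..n-1]``. Raises ``ValueError`` if the circulant embedding is not
    nonnegative definite (caller falls back to Cholesky synthesis).
    """
    m = 2 * (len(acov) - 1)
    row = np.concatenate([acov, acov[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise ValueError("circulant embedding not nonnegative definite")
    lam = np.clip(lam, 0.0, None)
    half = m // 2
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0]) * rng.normal()
    w[half] = np.sqrt(lam[half]) * rng.normal()
    zr = rng.normal(size=half - 1)
    zi = rng.normal(size=half - 1)
    w[1:half] = np.sqrt(lam[1:half] / 2.0) * (zr + 1j * zi)
    w[half + 1 :] = np.conj(w[half - 1 : 0 : -1])
    x = np.fft.fft(w) / np.sqrt(m)
    return x.real[:n]


def _fgn_cholesky(acov: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    cov = toeplitz(acov[:n])
    L = cholesky(cov + 1e-12 * acov[0] * np.eye(n), lower=True)
    return L @ rng.normal(size=n)


def generate_fbm(
    params: FBMParams, n_steps: int, dt: float, seed=None, traj_id: str = ""
) -> Trajectory:
    """Simulate fractional Brownian motion by exact covariance synthesis.

    Each axis is an independent FBM. Increments are drawn with their exact
    stationary autocovariance via Davies–Harte circulant embedding; if the
    embedding fails to be nonnegative definite, Cholesky factorization of the
    Toeplitz increment covariance is used instead (O(n²) memory, so only
    viable for shorter series — the failure is rare for 0 < alpha < 2).
    """
    _check_grid(n_steps, dt)
    rng = _rng(seed)
    n_incr = n_steps - 1
    acov = fbm_increment_autocovariance(params, dt, np.arange(n_incr + 1))
    pos = np.empty((n_steps, params.dim))
    pos[0] = 0.0
    for ax in range(params.dim):
        try:
            fgn = _fgn_davies_harte(acov, n_incr, rng)
        except ValueError:
            fgn = _fgn_cholesky(acov, n_incr, rng)
        pos[1:, ax] = np.cumsum(fgn)
    times = np.arange(n_steps) * dt
    return Trajectory(times=times, positions=pos, traj_id=traj_id)


def sample_sojourns(gamma: float, tau_c: float, tau_0: float, n: int, seed=None) -> np.ndarray:
    """Draw sojourn times from ``rho(tau) ∝ tau**(-1-gamma) exp(-tau/tau_c)``.

    Support is ``[tau_0, inf)``. Sampling is by rejection with a pure
    power-law (Pareto) proposal ``tau = tau_0 * U**(-1/gamma)`` and acceptance
    probability ``exp(-(tau - tau_0)/tau_c)``; the resulting draws follow the
    target density exactly (the proposal dominates the target up to the
    bounded factor ``exp(-(tau - tau_0)/tau_c) ≤ 1``).
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    if tau_0 <= 0 or tau_c <= 0:
        raise ValueError("tau_0 and tau_c must be positive")
    if tau_0 >= tau_c:
        warnings.warn(
            f"tau_0={tau_0} >= tau_c={tau_c}: cutoff-dominated regime, "
            "the power law is barely expressed",
            stacklevel=2,
        )
    rng = _rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        batch = min(max(4 * (n - filled), 64), 4_000_000)
        u = rng.uniform(size=batch)
        tau = tau_0 * u ** (-1.0 / gamma)
        accept = rng.uniform(size=batch) < np.exp(-(tau - tau_0) / tau_c)
        acc = tau[accept]
        take = min(len(acc), n - filled)
        out[filled : filled + take] = acc[:take]
        filled += take
    return out


def _draw_state_path(
    params: LEFDParams, duration: float, rng: np.random.Generator, p_start_fast: float = 0.5
) -> StateSeries:
    start_fast = bool(rng.uniform() < p_start_fast)
    laws = {
        "F": (params.gamma, params.tau_c),
        "S": (
            params.gamma_slow if params.gamma_slow is not None else params.gamma,
            params.tau_c_slow if params.tau_c_slow is not None else params.tau_c,
        ),
    }
    switch_times: list[float] = []
    labels: list[str] = []
    t, state = 0.0, ("F" if start_fast else "S")
    while t < duration:
        labels.append(state)
        g, tc = laws[state]
        tau = float(sample_sojourns(g, tc, params.tau_0, 1, rng)[0])
        t += tau
        if t < duration:
            switch_times.append(t)
        state = "S" if state == "F" else "F"
    return StateSeries(
        switch_times=np.array(switch_times), labels=tuple(labels), t_end=duration
    )


def generate_lefd(
    params: LEFDParams,
    n_steps: int,
    dt: float,
    seed=None,
    traj_id: str = "",
    p_start_fast: float = 0.5,
) -> tuple[Trajectory, StateSeries]:
    """Simulate the two-state fluctuating-diffusivity Langevin model.

    The diffusivity path ``D(t)`` alternates between ``d_fast`` and
    ``d_slow`` with sojourns drawn from the cut-off power law; positions
    advance as ``dx = sqrt(2 D(t)) dW`` per axis. Because a state switch
    generally falls inside a sampling step, each increment uses the
    time-averaged diffusivity over its step, which reproduces the exact
    increment variance ``2 ∫ D(t) dt`` of the piecewise-constant model.

    Returns the trajectory together with the ground-truth state path.
    """
    _check_grid(n_steps, dt)
    if not 0.0 <= p_start_fast <= 1.0:
        raise ValueError("p_start_fast must lie in [0, 1]")
    rng = _rng(seed)
    duration = (n_steps - 1) * dt

    states = _draw_state_path(params, duration, rng, p_start_fast)

    # cumulative fast-state occupancy -> time-averaged D per step
    knots_t = np.concatenate(([0.0], states.switch_times, [duration]))
    occ = np.array([1.0 if lab == "F" else 0.0 for lab in states.labels])
    knots_fast = np.concatenate(([0.0], np.cumsum(occ * np.diff(knots_t))))
    step_edges = np.arange(n_steps) * dt
    fast_cum = np.interp(step_edges, knots_t, knots_fast)
    frac_fast = np.diff(fast_cum) / dt
    d_step = d_um2s_to_nm2ns(
        frac_fast * params.d_fast + (1.0 - frac_fast) * params.d_slow
    )

    sigma = np.sqrt(2.0 * d_step * dt)
    incr = rng.normal(size=(n_steps - 1, params.dim)) * sigma[:, None]
    pos = np.vstack([np.zeros((1, params.dim)), np.cumsum(incr, axis=0)])
    traj = Trajectory(times=step_edges, positions=pos, traj_id=traj_id)
    return traj, states


def generate_bound_count(
    states: StateSeries,
    times: np.ndarray,
    level_fast: float,
    level_slow: float,
    noise_sd: float = 1.0,
    seed=None,
) -> CovariateSeries:
    """Emulate a bound-lipid count anti-correlated with the diffusive state.

    In the slow state more lipids are bound than in the fast state
    (``level_slow > level_fast``). The count at each grid time is the state
    level plus rounded Gaussian noise, clipped at zero.
    """
    if level_fast < 0 or level_slow <= level_fast:
        raise ValueError("need level_slow > level_fast >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = _rng(seed)
    times = np.asarray(times, dtype=float)
    labels = states.state_at(np.clip(times, 0.0, np.nextafter(states.t_end, 0.0)))
    base = np.where(labels == "F", float(level_fast), float(level_slow))
    noise = np.round(rng.normal(0.0, noise_sd, size=times.shape)) if noise_sd > 0 else 0.0
    values = np.clip(base + noise, 0.0, None)
    return CovariateSeries(times=times, values=values)


def bm_ensemble(D: float, n_traj: int, n_steps: int, dt: float, dim: int = 2, seed=None):
    """Ensemble of independent BM trajectories from spawned child seeds."""
    from .core import Ensemble

    seeds = spawn_seeds(seed, n_traj)
    return Ensemble(
        tuple(
            generate_bm(D, n_steps, dt, dim, seed=np.random.default_rng(s), traj_id=f"bm-{i}")
            for i, s in enumerate(seeds)
        )
    )


def fbm_ensemble(params: FBMParams, n_traj: int, n_steps: int, dt: float, seed=None):
    """Ensemble of independent FBM trajectories from spawned child seeds."""
    from .core import Ensemble

    seeds = spawn_seeds(seed, n_traj)
    return Ensemble(
        tuple(
            generate_fbm(params, n_steps, dt, seed=np.random.default_rng(s), traj_id=f"fbm-{i}")
            for i, s in enumerate(seeds)
        )
    )


def lefd_ensemble(params: LEFDParams, n_traj: int, n_steps: int, dt: float, seed=None):
    """Ensemble of independent LEFD trajectories plus their state paths."""
    from .core import Ensemble

    seeds = spawn_seeds(seed, n_traj)
    trajs, paths = [], []
    for i, s in enumerate(seeds):
        traj, st = generate_lefd(
            params, n_steps, dt, seed=np.random.default_rng(s), traj_id=f"lefd-{i}"
        )
        trajs.append(traj)
        paths.append(st)
    return Ensemble(tuple(trajs)), paths
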