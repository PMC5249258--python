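# Methods

This note documents the models, estimators and numerical choices behind
`fluctodiff`, and what the synthetic benchmarks do and do not demonstrate.

## Models

**Brownian motion.** Independent Gaussian increments per axis with variance
2·D·dt. D is given in μm²/s and converted internally with
1 μm²/s = 10⁻³ nm²/ns. The zero-diffusivity limit returns a static
trajectory.

**Fractional Brownian motion.** Each axis is an independent centered
Gaussian process with stationary increments and per-axis MSD
⟨x²(t)⟩ = k_α t^α (α = 2H; for α = 1 this is Brownian motion with
k_α = 2D). Increments are synthesized *exactly* from their autocovariance

    cov(k) = k_α dt^α (|k+1|^α − 2|k|^α + |k−1|^α)/2

by Davies–Harte circulant embedding: the covariance sequence is embedded in
a circulant matrix whose eigenvalues are obtained by FFT; complex Gaussian
amplitudes with those variances are transformed back, giving the exact joint
distribution in O(N log N). If the embedding is not nonnegative definite
(rare for 0 < α < 2; eigenvalues below −10⁻⁸ of the maximum) the generator
falls back to Cholesky factorization of the Toeplitz increment covariance,
which is exact but O(N²) and therefore only suitable for shorter series.
Subdiffusive FBM (α < 1) reproduces the antipersistent increments seen for
membrane-bound proteins at sub-crossover lags; the generator makes no
attempt to model the crossover to normal diffusion itself.

**Two-state fluctuating diffusivity (LEFD).** Overdamped Langevin dynamics
dx = √(2D(t)) dW per axis with D(t) switching dichotomously between D_F and
D_S. (The dynamics is written with the square root so that ⟨x²⟩ = 2Dt holds
in each state, consistent with the TAMSD normalization D = δ̄²/(2dΔ).)
Sojourn times are i.i.d. from the exponentially cut-off power law

    ρ(τ) ∝ τ^(−1−γ) exp(−τ/τ_c),  τ ≥ τ_0,

shared between the states by default (per-state γ/τ_c can be supplied);
the initial state is an even coin flip and the first sojourn starts fresh
at t = 0 (a renewal at the origin, not an equilibrium draw — immaterial for
the stationary-mean statistics tested here). Sampling is by rejection with
a Pareto proposal τ = τ_0 U^(−1/γ) and acceptance probability
exp(−(τ−τ_0)/τ_c), exact in distribution. Because a switch generally falls
inside a sampling step, each increment uses the time-averaged diffusivity
over its step, which reproduces the exact integrated variance 2∫D dt of the
piecewise-constant model; ground-truth switch times are returned alongside
the trajectory.

The lower cutoff τ_0 defaults to the sampling step dt — the smallest dwell
the simulation can resolve. The benchmark parameter set is D_F = 17 μm²/s,
D_S = 14 μm²/s, γ = 0.6, τ_c = 10 μs, the values obtained by fitting the two-state model to the RSD of a
membrane-bound protein's trajectories.

**Bound-count covariate.** A piecewise-constant count (higher level in the
slow state) plus rounded Gaussian noise, clipped at zero, emulating the
number of lipids bound to the protein. The level defaults used in the
examples (2 fast / 6 slow, unit noise) were chosen once so that the
segment-level correlation magnitude lands in the regime reported for real
trajectories; only the *sign* of the correlation is asserted anywhere,
since the magnitude is calibration-dependent by construction.

All generators are pure functions of (parameters, seed); ensembles spawn
per-trajectory child seeds from the master seed via `SeedSequence.spawn`,
so results are reproducible bitwise and members are independent.

## Estimators

**TAMSD (and EAMSD).** The time integral is discretized as the mean over
all overlapping displacement start indices; lags must be integer multiples
of dt (no interpolation — off-grid lags are rejected). The ensemble MSD
averages squared displacements from each member's own origin. Aging curves
restrict the TAMSD to data within measurement time t. Exponents are
unweighted least-squares slopes of log value vs log lag (log-spaced lag
grids roughly equalize the variance per point); the slope standard error is
reported. No drift is subtracted inside the estimators; a separate utility
removes a best-fit linear drift on request. Note that detrending a random
walk also removes genuine diffusion variance at lags comparable to the
observation time, so it should be applied only when a deterministic drift
is actually present.

**Displacement autocorrelation.** ⟨(x(t+Δ)−x(t))(x(Δ)−x(0))⟩/Δ², averaged
over ensemble members and, by default, over shifted time origins (the
processes in scope are stationary, so the two conventions estimate the same
quantity; the convention used is recorded in the output). Per-axis DAFs are
averaged. For t < Δ the two increments overlap and correlate positively
even for Brownian motion; the Brownian null C = 0 applies for t ≥ Δ.

**Propagator.** Displacements at one lag are pooled across axes, origins
and members (each axis is an independent copy of the same 1-D marginal; a
per-axis mode exists for strict single-coordinate replication), normalized
by their sample SD, and binned by the Freedman–Diaconis rule capped at 200
bins. The emitted density is renormalized so its trapezoidal integral on
the bin centers is exactly 1 — the same quadrature users will apply to it.
The non-Gaussian parameter uses the 1-D convention ⟨x⁴⟩/(3⟨x²⟩²) − 1.

**RSD of TAMSDs.** Population moments (divide by n) across the ensemble,
matching the angle-bracket notation; n is reported so users can correct if
desired. The default measurement-time grid is 8 log-spaced points per
decade from 10Δ to the trajectory duration. For 2-D Brownian motion the
small-Δ/t closed form is R ≈ √(4Δ/(3td)); it was verified here by
independent Monte Carlo before being used as a test reference.

A caution on the scaling window: over t/Δ ≲ 100 the fitted RSD slope of
*Brownian* motion itself comes out slightly below −1/2 (finite-Δ/t
corrections); the asymptote emerges only for Δ ≪ t. The statement "the
two-state model converges more slowly than the ergodic reference" is
therefore asserted as a *paired* comparison — LEFD slope above the slope of
a Brownian ensemble measured under identical conditions (same n, duration,
lag) — rather than against the literal constant −0.5, which both processes
undershoot on short windows. (Read physically, "slower than t^(-1/2)" means slower convergence than
the ergodic reference, which is exactly what the paired test asserts.)

**Short-time diffusivity segmentation.** Three stages, all deterministic
functions of (trajectory, Δ, T, T_c, Δ_short):

1. *Windowed diffusivity.* D(t; Δ, T) = [TAMSD over [t, t+T−Δ] at lag Δ]
   /(2dΔ), computed with a cumulative sum over squared displacements (O(N)
   total) on a stride-configurable grid of window starts. Window endpoints
   are inclusive (w+1 summands for a window of w steps). Defaults
   Δ = 0.1 μs, T = 1 μs.
2. *Renewal detection.* Candidates are strict sign changes of D − D_a
   between consecutive grid points (D_a = whole-series mean, recomputed per
   trajectory); the renewal time is the earlier grid point — no sub-grid
   interpolation. A candidate is confirmed by the forward occupation
   fractions over [t_i, t_i+T_c]: ρ_F (fraction with D > D_a) must exceed
   ρ_S for an upward (S→F) crossing, mirrored for F→S. Candidates falling
   inside an already-confirmed renewal's confirmation window are skipped
   (prevents double-counting one transition), and confirmations that fail
   to alternate direction are dropped keeping the first. A confirmation
   window running past the series end is evaluated truncated and flagged.
   Default T_c = 10 ns — two orders of magnitude below T = 1 μs; the scale
   mismatch is deliberate, the confirmation probing a much finer timescale
   than the estimation window. Both are configurable. T_c is resolved by the stride-dt
   grid of stage 1, so very coarse strides blunt the confirmation test.
3. *Per-segment diffusivity.* Each inter-renewal segment gets the windowed
   TAMSD at a much shorter lag (default 0.1 ns) over 2dΔ. Segments shorter
   than twice the short lag — including renewals on the trajectory
   boundaries — are merged into their left neighbor and counted in the
   result (a rule this implementation defines). Segments are
   labeled fast/slow by comparing their diffusivity with D_a.

The per-segment covariate correlation is an ordinary Pearson r between
segment diffusivities and segment-mean covariate values (≥ 3 segments
required).

**Sojourn-law MLE.** The density ∝ τ^(−1−γ)e^(−τ/τ_c) truncated at τ_0 has
normalizer τ_c^(−γ) Γ(−γ, τ_0/τ_c); the upper incomplete gamma at negative
shape is computed by the recurrence Γ(a,x) = (Γ(a+1,x) − x^a e^(−x))/a down
from positive shape (validated against numerical quadrature). The negative
log-likelihood reduces to sufficient statistics (Σlog τ, Στ), so each
evaluation is O(1); it is minimized over (γ, log τ_c) with bounded
Nelder–Mead from γ = 0.5, τ_c = max(τ) (derivative-free, because near the
γ → 0 boundary the normalizer's numerical gradient suffers cancellation).
Bounds are γ ∈ [10⁻⁶, 1.99] and log τ_c ∈ [log τ_0, log max(τ) + 15].
Standard errors come from the observed information (central-difference
Hessian, step 10⁻⁴), with the delta method for τ_c; non-convergence raises
with the optimizer diagnostics rather than returning a silent fallback.
Fitting a purely exponential sample drives γ̂ to the lower bound, as it
should. Note that sojourns harvested from finite trajectories are
right-censored, which biases τ̂_c low when τ_c is comparable to the
trajectory length (visible in the worked example); the benchmark recovery
test therefore draws directly from the law.

## Benchmark scales and what they show

The acceptance workflows (`fluctodiff.workflows`, driven by
`scripts/acceptance.py`) use: 50 FBM trajectories of 2¹⁵ steps at 0.1 ns
(TAMSD exponent fit over lags 0.2–10 ns, ≈16 points/decade); 500 Brownian
trajectories of 2¹⁴ steps at 1 ns (RSD at Δ = 10 ns on 8 log-spaced times
over the top decade); 10⁴ sojourn draws (γ = 0.6, τ_c = 10 μs, τ_0 = 1 ns);
and 100 two-state trajectories of 8 μs at 0.1 ns, with the windowed
diffusivity evaluated on a 1-ns strided grid — every strided point is the
same unbiased window estimate, so striding thins correlated summands
without moving the conditional means. State-conditioned means average
D(t; Δ, T) over all window positions whose full extent lies inside a single
ground-truth sojourn of that state.

These synthetic benchmarks validate the *estimators* under the generating
models — unbiasedness, exponent recovery, detection of well-separated
states. They do not validate the models against real membrane-protein
data: real trajectories superpose the FBM-like short-lag regime and the
fluctuating diffusivity (the generators here produce each in isolation),
their crossover behavior has no closed form, and quantities tied to the
original MD data (crossover location, propagator σ values, the −0.42
covariate correlation) are qualitative anchors only. With D_F/D_S = 17/14
the two states overlap heavily at the single-window level, so per-segment
state calls on real-scale data are noisy even when the conditional means
are recovered accurately; detection-rate guarantees are only claimed for
well-separated states (ratio ≥ 5, sojourns ≫ T).

## Known limitations

- No spatially heterogeneous (quenched-disorder) diffusivity generator,
  and no hidden-Markov or Bayesian change-point alternatives to the
  renewal method.
- No automatic crossover detection in MSD curves; fit windows are explicit.
- The FBM Cholesky fallback is O(N²) and impractical beyond ~10⁴ steps.
- Binary MD formats are out of scope; trajectories enter as delimited text
  with declared units (ns/nm, with μs/Å conversion on read).
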