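# fluctodiff

Trajectory statistics for anomalous diffusion and temporally fluctuating
diffusivity, aimed at single-particle trajectories of membrane-bound
proteins and similar tracked particles (from coarse-grained MD center-of-mass
tables, single-particle tracking, or simulation).

A protein bound to a lipid membrane does not diffuse with one constant
diffusion coefficient. At sub-10-ns lags its increments anticorrelate like
fractional Brownian motion (FBM), inherited from the lipids it touches; on
longer scales its *short-time* diffusivity switches between faster and
slower values as the number of bound lipids changes. `fluctodiff`
implements the statistics needed to detect and quantify both effects, and
synthetic generators to validate every stage.

## What it computes

For a trajectory r(t) observed for time *t*:

- **TAMSD** (time-averaged mean squared displacement),
  δ̄²(Δ; t) = 1/(t−Δ) ∫₀^{t−Δ} [r(t′+Δ) − r(t′)]² dt′, and its power-law
  exponent α (δ̄² ∝ Δ^α; α < 1 is subdiffusion), plus the ensemble-averaged
  MSD, aging curves and D = δ̄²(Δ)/(2dΔ).
- **Displacement autocorrelation** C_Δ(t) = ⟨(x(t+Δ)−x(t))(x(Δ)−x(0))⟩/Δ²,
  with the exact FBM reference ((t+Δ)^α − 2t^α + |t−Δ|^α)/(2Δ^α) and its
  tail −(α−α²)(Δ/t)^{2−α}/2.
- **Propagators**: SD-normalized displacement histograms against the unit
  Gaussian, and the non-Gaussian parameter ⟨x⁴⟩/(3⟨x²⟩²) − 1.
- **Ergodicity diagnostics**: the relative standard deviation (RSD) of
  TAMSDs across an ensemble, R(t; Δ) = √(⟨δ̄²²⟩−⟨δ̄²⟩²)/⟨δ̄²⟩, which decays
  as t^{−1/2} for ergodic homogeneous diffusion and more slowly when the
  diffusivity itself persists in time.
- **Short-time diffusivity segmentation**: a windowed diffusivity
  D(t; Δ, T) (TAMSD restricted to [t, t+T−Δ], over 2dΔ), renewal times
  where D(t) crosses its trajectory mean D_a confirmed by forward
  occupation fractions over a window T_c, and per-segment short-lag
  diffusion coefficients — recovering the piecewise diffusivity path
  without knowing the switch times in advance.
- **Synthetic models**: Brownian motion; exact FBM (Davies–Harte circulant
  embedding); a two-state Langevin model with fluctuating diffusivity
  (dx = √(2D(t)) dW, D(t) ∈ {D_F, D_S}) whose sojourn times follow
  ρ(τ) ∝ τ^{−1−γ} e^{−τ/τ_c}, with maximum-likelihood refitting of (γ, τ_c);
  and a bound-lipid-count covariate anti-correlated with the state.

Units: positions nm, times ns, diffusivities reported in μm²/s
(1 nm²/ns = 10³ μm²/s).

## Worked example

Segment one two-state trajectory (8 μs at 0.1-ns sampling, fast/slow
diffusivities 17 and 14 μm²/s, sojourn law γ = 0.6, τ_c = 10 μs):

```python
import fluctodiff as fd

params = fd.LEFDParams(d_fast=17.0, d_slow=14.0, gamma=0.6, tau_c=1.0e4, tau_0=1.0)
traj, states = fd.generate_lefd(params, 80_001, 0.1, seed=61)
series, detection, result = fd.segment_trajectory(
    traj, lag_ns=100.0, window_ns=1000.0, t_c=10.0, short_lag_ns=0.1, stride=10)
```

Running `python examples/06_segmentation_pipeline.py` (which adds the
bound-count covariate and a sojourn-law refit) prints:

```
temporal diffusivity: 7001 windows, D_a = 15.11 μm²/s
renewals: 11 candidate crossings, 11 confirmed
segments: 12 (2 fast / 10 slow), D range 13.5–17.0 μm²/s
segment diffusivity vs bound count: Pearson r = -0.97 over 12 segments (negative: more bound lipids → slower)
sojourn-law fit from 5529 sojourns: γ̂ = 0.60 ± 0.01 (input 0.6), τ̂_c = 4.1 μs (input 10)
```

D_a is the whole-trajectory mean of the windowed diffusivity; the 12
segments between confirmed renewals carry short-time diffusivities spanning
the two generating values; the negative Pearson r recovers the built-in
anticorrelation between diffusivity and bound-lipid count; and the
maximum-likelihood fit recovers the sojourn exponent exactly (τ_c is
under-estimated here because 10-μs sojourns are censored by the 8-μs
trajectories). The other scripts in `examples/` each exercise one
capability (model generation, TAMSD exponents, displacement
autocorrelation, propagators, RSD) and print what the numbers mean.

A thin CLI mirrors the library: `fluctodiff simulate|tamsd|eamsd|aging|daf|
propagator|rsd|rsd-compare|segment|fit-sojourns` operate on
self-describing TSV trajectories and JSON ensemble manifests.

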