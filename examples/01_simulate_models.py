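"""Generate the three synthetic diffusion models and summarize them.

Brownian motion is the homogeneous reference; fractional Brownian motion
reproduces the anticorrelated short-lag regime of lipid-mediated motion;
the two-state fluctuating-diffusivity model switches between a fast and a
slow short-time diffusivity with heavy-tailed sojourns.
"""

import numpy as np

import fluctodiff as fd

bm = fd.generate_bm(D=15.0, n_steps=20_001, dt=0.1, seed=1)
print(f"BM:   {bm.n_steps} samples, dt = {bm.dt} ns, "
      f"rms displacement {np.sqrt(np.sum(bm.positions[-1]**2)):.2f} nm after {bm.duration/1e3:.1f} μs")

fbm = fd.generate_fbm(fd.FBMParams(alpha=0.7, k_alpha=0.03), n_steps=20_001, dt=0.1, seed=2)
incr = np.diff(fbm.positions[:, 0])
rho1 = np.mean(incr[1:] * incr[:-1]) / np.mean(incr**2)
print(f"FBM:  lag-1 increment autocorrelation {rho1:+.3f} "
      f"(negative = antipersistent, theory {(2**0.7 - 2)/2:+.3f} for α = 0.7)")

params = fd.LEFDParams(d_fast=17.0, d_slow=14.0, gamma=0.6, tau_c=1.0e4, tau_0=1.0)
lefd, states = fd.generate_lefd(params, n_steps=80_001, dt=0.1, seed=3)
frac_fast = np.mean(states.state_at(lefd.times) == "F")
print(f"LEFD: {len(states.labels)} sojourns over {lefd.duration/1e3:.0f} μs, "
      f"{100*frac_fast:.0f}% of time in the fast state, "
      f"median sojourn {np.median(states.sojourns):.1f} ns")
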