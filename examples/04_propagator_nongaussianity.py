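"""Displacement distributions and non-Gaussianity of mixed diffusivities.

Homogeneous diffusion gives Gaussian displacements at every lag; switching
between two diffusivities makes the SD-normalized propagator heavier-tailed
than the unit Gaussian, quantified by ⟨x⁴⟩/(3⟨x²⟩²) - 1.
"""

import numpy as np
from scipy import stats

import fluctodiff as fd

bm = fd.bm_ensemble(15.0, 20, 4001, 1.0, seed=41)
ng_bm = fd.nongaussian_parameter(fd.pooled_displacements(bm, 10.0))

params = fd.LEFDParams(d_fast=30.0, d_slow=3.0, gamma=0.6, tau_c=1.0e4, tau_0=1.0)
lefd, _ = fd.lefd_ensemble(params, 20, 4001, 1.0, seed=42)
x = fd.pooled_displacements(lefd, 10.0)
ng_lefd = fd.nongaussian_parameter(x)

hist = fd.displacement_histogram(lefd, 10.0)
tail = np.mean(np.abs(x / x.std()) > 4.0)
tail_gauss = 2 * stats.norm.sf(4.0)

print(f"non-Gaussian parameter:  BM {ng_bm:+.4f}   two-state {ng_lefd:+.4f}")
print(f"propagator σ = {hist.sigma:.3f} nm at Δ = 10 ns; histogram area = {hist.integral:.6f}")
print(f"mass beyond 4σ: observed {tail:.2e} vs Gaussian {tail_gauss:.2e} "
      f"({tail/tail_gauss:.1f}x excess)")
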