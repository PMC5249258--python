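"""Ergodicity diagnostics: RSD of TAMSDs for Brownian vs two-state motion.

For Brownian motion the trajectory-to-trajectory scatter of the TAMSD
decays as t^(-1/2); persistent diffusivity states slow this decay below the
sojourn cutoff even though the process remains ergodic.
"""

import numpy as np

import fluctodiff as fd

t_grid = np.unique(np.round(np.logspace(np.log10(500), np.log10(8000), 10))).astype(float)

bm = fd.bm_ensemble(15.0, 200, 8001, 1.0, seed=51)
slope_bm, se_bm = fd.fit_rsd_exponent(fd.rsd(bm, 100.0, t_grid))

params = fd.LEFDParams(d_fast=17.0, d_slow=14.0, gamma=0.6, tau_c=1.0e4, tau_0=1.0)
lefd, _ = fd.lefd_ensemble(params, 200, 8001, 1.0, seed=52)
slope_lefd, se_lefd = fd.fit_rsd_exponent(fd.rsd(lefd, 100.0, t_grid))

ratio = fd.ergodicity_ratio(lefd, [10.0, 100.0, 1000.0])

print(f"RSD exponent, Brownian:  {slope_bm:+.3f} ± {se_bm:.3f}  (ergodic reference: -0.5)")
print(f"RSD exponent, two-state: {slope_lefd:+.3f} ± {se_lefd:.3f}  "
      "(above the matched Brownian slope: slower convergence)")
print("TAMSD/EAMSD ratio at Δ = 10, 100, 1000 ns:",
      np.array2string(ratio, precision=3), "→ ergodic (≈ 1)")
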