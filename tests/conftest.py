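import numpy as np
import pytest

import fluctodiff as fd

FIG4_PARAMS = dict(d_fast=17.0, d_slow=14.0, gamma=0.6, tau_c=1.0e4)


@pytest.fixture(scope="session")
def bm_ensemble_small():
    """200 Brownian trajectories, D = 15 μm²/s, 2^12 steps of 1 ns."""
    return fd.bm_ensemble(15.0, 200, 2**12, 1.0, seed=101)


@pytest.fixture(scope="session")
def fbm_traj_07():
    """One long subdiffusive FBM trajectory (α = 0.7)."""
    return fd.generate_fbm(fd.FBMParams(alpha=0.7, k_alpha=0.03), 2**15, 0.1, seed=202)


@pytest.fixture(scope="session")
def lefd_fig4():
    """40 two-state trajectories with the fitted fast/slow parameter set, 4 μs at 1 ns."""
    params = fd.LEFDParams(tau_0=1.0, dim=2, **FIG4_PARAMS)
    return fd.lefd_ensemble(params, 40, 4001, 1.0, seed=303)


def ballistic_trajectory(v=0.2, n=200, dt=1.0, dim=2):
    t = np.arange(n) * dt
    pos = np.stack([v * t] * dim, axis=1)
    return fd.Trajectory(times=t, positions=pos, traj_id="ballistic")
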