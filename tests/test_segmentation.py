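"""Renewal-time segmentation: window oracles, detection benchmarks, MLE."""

import numpy as np
import pytest
from scipy import integrate

import fluctodiff as fd
from fluctodiff.segmentation import (
    TemporalDiffusivitySeries,
    sojourn_log_normalizer,
)
from fluctodiff.units import d_nm2ns_to_um2s

from conftest import FIG4_PARAMS, ballistic_trajectory


def temporal_diffusivity_brute(traj, lag_ns, window_ns):
    """Double-loop oracle for the windowed diffusivity series."""
    m = int(round(lag_ns / traj.dt))
    w = int(round((window_ns - lag_ns) / traj.dt))
    pos = traj.positions
    out = []
    for j in range(traj.n_steps - 1 - m - w + 1):
        total = 0.0
        for i in range(j, j + w + 1):
            d = pos[i + m] - pos[i]
            total += float(np.dot(d, d))
        out.append(total / (w + 1) / (2 * traj.dim * lag_ns))
    return d_nm2ns_to_um2s(np.array(out))


class TestTemporalDiffusivity:
    def test_ballistic_constant_closed_form(self):
        v, lag = 0.3, 5.0
        traj = ballistic_trajectory(v=v, n=400, dt=1.0)
        series = fd.temporal_diffusivity(traj, lag, 50.0)
        # |r(t+Δ)-r(t)|² = d v²Δ² → D = v²Δ/(2d)·(d/d) = v²Δ/2 per the 2dΔ divisor
        expected = d_nm2ns_to_um2s(2 * v**2 * lag**2 / (2 * 2 * lag))
        assert series.values == pytest.approx(np.full(len(series.values), expected), rel=1e-12)

    def test_static_trajectory_is_zero(self):
        traj = fd.Trajectory(times=np.arange(100.0), positions=np.full((100, 2), 3.0))
        series = fd.temporal_diffusivity(traj, 2.0, 20.0)
        assert np.all(series.values == 0.0)

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        traj = fd.Trajectory(
            times=np.arange(150.0), positions=np.cumsum(rng.normal(size=(150, 2)), axis=0)
        )
        series = fd.temporal_diffusivity(traj, 4.0, 40.0)
        oracle = temporal_diffusivity_brute(traj, 4.0, 40.0)
        assert series.values == pytest.approx(oracle, rel=1e-10)

    def test_bm_time_mean_unbiased(self, bm_ensemble_small):
        means = [
            fd.temporal_diffusivity(t, 10.0, 100.0, stride=8).d_a
            for t in bm_ensemble_small[:100]
        ]
        means = np.array(means)
        se = means.std() / np.sqrt(len(means))
        assert abs(means.mean() - 15.0) < 3 * se

    def test_window_must_exceed_lag(self):
        traj = ballistic_trajectory(n=200)
        with pytest.raises(ValueError, match="must exceed lag"):
            fd.temporal_diffusivity(traj, 10.0, 10.0)


def _series_from_values(values, dt=1.0):
    return TemporalDiffusivitySeries(
        t_grid=np.arange(len(values)) * dt, values=np.asarray(values, dtype=float),
        lag=1.0, window=10.0,
    )


class TestRenewalDetection:
    def test_constant_series_has_no_crossings(self):
        det = fd.detect_renewal_times(_series_from_values(np.full(100, 3.0)), t_c=5.0)
        assert det.candidate_times.size == 0
        assert det.confirmed_times.size == 0

    def test_noise_free_step_detected_at_the_step(self):
        # D = 1 for t < 50, D = 3 after: exactly one confirmed S→F renewal
        values = np.where(np.arange(100) < 50, 1.0, 3.0)
        det = fd.detect_renewal_times(_series_from_values(values), t_c=10.0)
        assert len(det.confirmed_times) == 1
        assert det.directions == ("SF",)
        assert abs(det.confirmed_times[0] - 49.0) <= 1.0  # earlier grid point
    def test_downward_step_is_fs(self):
        values = np.where(np.arange(100) < 50, 3.0, 1.0)
        det = fd.detect_renewal_times(_series_from_values(values), t_c=10.0)
        assert det.directions == ("FS",)

    def test_confirmed_renewals_alternate_and_bounded_by_candidates(self):
        rng = np.random.default_rng(29)
        values = 10 + np.cumsum(rng.normal(size=500)) * 0.3
        det = fd.detect_renewal_times(_series_from_values(values), t_c=8.0)
        assert len(det.confirmed_times) <= len(det.candidate_times)
        for a, b in zip(det.directions, det.directions[1:]):
            assert a != b

    def test_well_separated_states_mostly_matched(self):
        # piecewise-constant D with 5x ratio and sojourns ≫ T: ≥90% of the
        # true switches have a confirmed renewal within T + T_c
        rng = np.random.default_rng(31)
        dt, n = 1.0, 40_001
        period = 5000
        d_states = np.where((np.arange(n - 1) // period) % 2 == 0, 0.025, 0.005)
        incr = rng.normal(size=(n - 1, 2)) * np.sqrt(2 * d_states * dt)[:, None]
        pos = np.vstack([np.zeros((1, 2)), np.cumsum(incr, axis=0)])
        traj = fd.Trajectory(times=np.arange(n) * dt, positions=pos)
        series = fd.temporal_diffusivity(traj, 100.0, 1000.0)
        det = fd.detect_renewal_times(series, t_c=10.0)
        true_switches = np.arange(period, n - 1, period) * dt
        matched = sum(
            np.any(np.abs(det.confirmed_times - ts) <= 1000.0 + 10.0)
            for ts in true_switches
            if ts < series.t_grid[-1]
        )
        considered = np.sum(true_switches < series.t_grid[-1])
        assert matched / considered >= 0.9


class TestSegmentDiffusivity:
    def test_single_segment_equals_global_estimate(self):
        rng = np.random.default_rng(37)
        traj = fd.Trajectory(
            times=np.arange(300.0), positions=np.cumsum(rng.normal(size=(300, 2)), axis=0)
        )
        res = fd.segment_diffusivity(traj, [], short_lag_ns=1.0)
        expected = fd.diffusion_coefficient(fd.tamsd(traj, [1.0]), 1.0, 2)
        assert res.n_segments == 1
        assert res.segment_d[0] == pytest.approx(expected, rel=1e-12)

    def test_per_segment_values_equal_brute_force(self):
        rng = np.random.default_rng(41)
        traj = fd.Trajectory(
            times=np.arange(200.0), positions=np.cumsum(rng.normal(size=(200, 2)), axis=0)
        )
        renewals = [60.0, 140.0]
        res = fd.segment_diffusivity(traj, renewals, short_lag_ns=1.0)
        pos, m = traj.positions, 1
        for i, (a, b) in enumerate(zip([0, 60, 140], [60, 140, 199])):
            total, count = 0.0, 0
            for j in range(a, b + 1 - m):
                d = pos[j + m] - pos[j]
                total += float(np.dot(d, d))
                count += 1
            oracle = d_nm2ns_to_um2s(total / count / (2 * 2 * 1.0))
            assert res.segment_d[i] == pytest.approx(oracle, rel=1e-12)

    def test_short_segments_are_merged(self):
        rng = np.random.default_rng(43)
        traj = fd.Trajectory(
            times=np.arange(100.0), positions=np.cumsum(rng.normal(size=(100, 2)), axis=0)
        )
        res = fd.segment_diffusivity(traj, [50.0, 51.0], short_lag_ns=1.0)
        assert res.n_merged == 1
        assert res.n_segments == 2

    def test_labels_reflect_comparison_with_global_mean(self):
        rng = np.random.default_rng(47)
        traj = fd.Trajectory(
            times=np.arange(500.0), positions=np.cumsum(rng.normal(size=(500, 2)), axis=0)
        )
        res = fd.segment_diffusivity(traj, [100.0, 250.0, 400.0], short_lag_ns=1.0)
        for lab, d in zip(res.labels, res.segment_d):
            assert lab == ("F" if d > res.d_a else "S")

    def test_no_spurious_bimodality_on_homogeneous_bm(self, bm_ensemble_small):
        # segment D values on constant-D trajectories scatter unimodally
        # around the truth with the windowed-TAMSD sampling variance
        ds = []
        for traj in bm_ensemble_small[:40]:
            _, _, res = fd.segment_trajectory(
                traj, lag_ns=10.0, window_ns=100.0, t_c=10.0, short_lag_ns=1.0, stride=4
            )
            ds.extend(res.segment_d)
        ds = np.array(ds)
        assert abs(np.median(ds) - 15.0) / 15.0 < 0.1
        # unimodality proxy: central quartiles are not separated into clusters
        q1, q2, q3 = np.percentile(ds, [25, 50, 75])
        assert (q3 - q1) / q2 < 0.5

    def test_lefd_segments_track_ground_truth_states(self, lefd_fig4):
        # segments dominated by the true fast state should carry higher
        # short-time D than those dominated by the true slow state
        ens, states_list = lefd_fig4
        ds, true_frac_fast = [], []
        for traj, states in zip(ens.trajectories[:20], states_list[:20]):
            _, det, res = fd.segment_trajectory(
                traj, lag_ns=100.0, window_ns=1000.0, t_c=10.0, short_lag_ns=1.0, stride=1
            )
            for a, b, d in zip(res.bounds[:-1], res.bounds[1:], res.segment_d):
                mid = np.linspace(a, min(b, states.t_end * 0.999999), 50)
                ds.append(d)
                true_frac_fast.append(np.mean(states.state_at(mid) == "F"))
        ds, true_frac_fast = np.array(ds), np.array(true_frac_fast)
        mostly_f = true_frac_fast > 0.8
        mostly_s = true_frac_fast < 0.2
        assert mostly_f.sum() > 5 and mostly_s.sum() > 5
        assert ds[mostly_f].mean() > ds[mostly_s].mean()


class TestCovariateCorrelation:
    def _segmented(self, seed=53):
        rng = np.random.default_rng(seed)
        traj = fd.Trajectory(
            times=np.arange(600.0), positions=np.cumsum(rng.normal(size=(600, 2)), axis=0)
        )
        return fd.segment_diffusivity(traj, [150.0, 300.0, 450.0], short_lag_ns=1.0)

    def test_negated_covariate_gives_minus_one(self):
        res = self._segmented()
        times = np.arange(0.0, 600.0)
        # covariate constant per segment at the negation of segment D
        values = np.empty_like(times)
        offset = res.segment_d.max() + 1
        for a, b, d in zip(res.bounds[:-1], res.bounds[1:], res.segment_d):
            values[(times >= a) & (times <= b)] = offset - d
        cov = fd.CovariateSeries(times=times, values=values)
        r, n = fd.correlate_with_covariate(res, cov)
        assert n == 4
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_independent_covariate_near_zero(self):
        rs = []
        for seed in range(40):
            res = self._segmented(seed=seed)
            rng = np.random.default_rng(seed + 1000)
            times = np.arange(0.0, 600.0)
            cov = fd.CovariateSeries(times=times, values=rng.uniform(0, 10, times.size))
            r, _ = fd.correlate_with_covariate(res, cov)
            rs.append(r)
        assert abs(np.mean(rs)) < 3 / np.sqrt(4 * len(rs))

    def test_lefd_with_bound_count_is_negative(self, lefd_fig4):
        ens, states_list = lefd_fig4
        all_d, all_cov = [], []
        for traj, states in zip(ens.trajectories[:20], states_list[:20]):
            cov = fd.generate_bound_count(
                states, traj.times, level_fast=2, level_slow=6, noise_sd=1.0, seed=61
            )
            _, det, res = fd.segment_trajectory(
                traj, lag_ns=100.0, window_ns=1000.0, t_c=10.0,
                short_lag_ns=1.0, stride=1, covariate=cov,
            )
            all_d.extend(res.segment_d)
            all_cov.extend(res.covariate_means)
        r = np.corrcoef(all_d, all_cov)[0, 1]
        assert r < 0

    def test_too_few_segments_rejected(self):
        rng = np.random.default_rng(59)
        traj = fd.Trajectory(
            times=np.arange(100.0), positions=np.cumsum(rng.normal(size=(100, 2)), axis=0)
        )
        res = fd.segment_diffusivity(traj, [50.0], short_lag_ns=1.0)
        cov = fd.CovariateSeries(times=np.arange(100.0), values=np.ones(100))
        with pytest.raises(ValueError, match="at least 3 segments"):
            fd.correlate_with_covariate(res, cov)


class TestSojournFit:
    def test_normalizer_matches_quadrature(self):
        for g, tc, t0 in [(0.6, 1e4, 1.0), (0.2, 100.0, 0.5), (1.4, 1e3, 2.0)]:
            z, _ = integrate.quad(
                lambda u: u ** (-1 - g) * np.exp(-u / tc), t0, np.inf, limit=200
            )
            assert sojourn_log_normalizer(g, tc, t0) == pytest.approx(np.log(z), abs=1e-9)

    def test_parameter_recovery_within_3se(self):
        tau = fd.sample_sojourns(0.6, 1.0e4, 1.0, 10_000, seed=71)
        fit = fd.fit_sojourn_distribution(tau, 1.0)
        assert fit.converged
        assert abs(fit.gamma - 0.6) < 3 * fit.se_gamma
        assert abs(fit.tau_c - 1.0e4) < 3 * fit.se_tau_c

    def test_exponential_boundary_sample_converges(self):
        rng = np.random.default_rng(73)
        tau = 1.0 + rng.exponential(scale=50.0, size=5000)
        fit = fd.fit_sojourn_distribution(tau, 1.0)
        assert fit.converged
        assert fit.gamma < 0.2  # pushed to the power-law-free boundary

    def test_support_violation_rejected(self):
        with pytest.raises(ValueError, match="tau_0"):
            fd.fit_sojourn_distribution(np.linspace(0.5, 10, 200), 1.0)


def test_pipeline_is_deterministic(lefd_fig4):
    ens, _ = lefd_fig4
    traj = ens[0]
    out1 = fd.segment_trajectory(traj, 100.0, 1000.0, 10.0, 1.0, stride=2)
    out2 = fd.segment_trajectory(traj, 100.0, 1000.0, 10.0, 1.0, stride=2)
    assert np.array_equal(out1[2].segment_d, out2[2].segment_d)
    assert np.array_equal(out1[1].confirmed_times, out2[1].confirmed_times)
    assert out1[2].labels == out2[2].labels
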