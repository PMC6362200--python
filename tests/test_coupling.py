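"""Firing/acceleration coupling: paired bins, regressions, lag scan,
onset detection and cross-correlograms."""

import numpy as np
import pytest

import lcmaze as lm
from lcmaze.coupling import (
    OnsetSet,
    _upward_crossings,
    exclusion_windows,
)
from conftest import manual_session


@pytest.fixture(scope="module")
def coupled_session():
    cfg = lm.SimConfig(n_trials=60, seed=42, vc_on_gain=1.0, vc_off_gain=1.0,
                       reward_suppression=1.0, accel_coupling=0.25,
                       firing_lead_delta=0.035)
    s = lm.simulate_session(cfg)
    return s, lm.session_kinematics(s)


class TestEventBins:
    def test_at_most_ten_bins_per_anchor(self, coupled_session):
        s, kin = coupled_session
        pb = lm.collect_event_bins(s, kind="VC_ON_PD", kin=kin)
        assert pb.n <= 10 * s.n_trials
        assert pb.n > 0

    def test_silent_unit_yields_no_bins(self, coupled_session):
        s, kin = coupled_session
        silent = lm.Session(
            maze=s.maze,
            spikes=[lm.SpikeTrain("u0", np.array([]), waveform_ms=0.9)],
            tracking=s.tracking, events=s.events, trials=s.trials,
            blocks=s.blocks)
        pb = lm.collect_event_bins(silent, kind="VC_ON_PD", kin=kin)
        assert pb.n == 0  # every empty bin is below 0.1 Hz

    def test_values_match_bruteforce(self, coupled_session):
        s, kin = coupled_session
        pb = lm.collect_event_bins(s, kind="RWD_PD", kin=kin)
        t = s.spikes[0].times
        at, av = kin.times[kin.valid], kin.accel[kin.valid]
        for k in range(0, pb.n, max(1, pb.n // 40)):
            t0 = pb.times[k]
            assert pb.rate[k] == pytest.approx(
                ((t >= t0) & (t < t0 + 0.2)).sum() / 0.2)
            sel = (at >= t0) & (at < t0 + 0.2)
            assert pb.accel[k] == pytest.approx(av[sel].mean())

    def test_rate_floor_applied(self, coupled_session):
        s, kin = coupled_session
        pb = lm.collect_event_bins(s, kind="VC_ON_PD", kin=kin)
        assert (pb.rate >= 0.1).all()


class TestRegression:
    def test_perfectly_coupled_bins(self):
        accel = np.linspace(0.5, 10, 50)
        pb = lm.PairedBins("VC_ON_PD", np.arange(50.0), accel.copy(),
                           accel.copy(), lm.zscore(accel), lm.zscore(accel),
                           5)
        reg = lm.regress_rate_on_accel(pb)
        assert reg.r == pytest.approx(1.0)
        assert reg.slope == pytest.approx(1.0)

    def test_coupled_generator_positive_slope(self, coupled_session):
        s, kin = coupled_session
        pb = lm.collect_event_bins(s, kind="VC_ON_PD", kin=kin)
        reg = lm.regress_rate_on_accel(pb)
        assert reg.slope > 0 and reg.p < 0.05

    def test_positive_only_filter(self, coupled_session):
        s, kin = coupled_session
        pb = lm.collect_event_bins(s, kind="VC_ON_PD", kin=kin)
        reg = lm.regress_rate_on_accel(pb, positive_only=True)
        assert reg.n == int((pb.accel > 0).sum())

    def test_too_few_bins_raises(self):
        pb = lm.PairedBins("VC_ON_PD", np.array([0.0]), np.array([1.0]),
                           np.array([1.0]), np.array([np.nan]),
                           np.array([np.nan]), 1)
        with pytest.raises(ValueError):
            lm.regress_rate_on_accel(pb)


class TestOutsideBins:
    def test_bins_avoid_exclusion_windows(self, coupled_session):
        s, kin = coupled_session
        pb = lm.collect_outside_bins(s, kin=kin)
        merged = exclusion_windows(s)
        for t0 in pb.times:
            for a, b in merged:
                assert not (t0 < b and t0 + 0.1 > a)

    def test_downsampling_matches_n_and_is_reproducible(self,
                                                        coupled_session):
        s, kin = coupled_session
        pb1 = lm.collect_outside_bins(
            s, match_n=200, rng=np.random.default_rng(9), kin=kin)
        pb2 = lm.collect_outside_bins(
            s, match_n=200, rng=np.random.default_rng(9), kin=kin)
        assert pb1.n == 200
        assert np.array_equal(pb1.times, pb2.times)

    def test_insufficient_supply_uses_all(self, coupled_session):
        s, kin = coupled_session
        pb = lm.collect_outside_bins(
            s, match_n=10**6, rng=np.random.default_rng(0), kin=kin)
        assert 0 < pb.n < 10**6

    def test_outside_regression_significant_for_global_coupling(
            self, coupled_session):
        s, kin = coupled_session
        pb = lm.collect_outside_bins(
            s, match_n=2000, rng=np.random.default_rng(1), kin=kin)
        reg = lm.regress_rate_on_accel(pb)
        assert reg.slope > 0 and reg.p < 0.05


class TestLagScan:
    def test_recovers_100ms_lead(self):
        cfg = lm.SimConfig(n_trials=100, seed=77, vc_on_gain=1.0,
                           vc_off_gain=1.0, reward_suppression=1.0,
                           accel_coupling=0.25, firing_lead_delta=0.1)
        s = lm.simulate_session(cfg)
        ls = lm.lag_scan(s, kind="VC_ON_PD")
        assert abs(ls.best_shift_ms - 100.0) <= 20.0
        assert ls.shifts_ms[0] == -1000.0 and ls.shifts_ms[-1] == 1000.0

    def test_best_shift_on_grid(self, coupled_session):
        s, kin = coupled_session
        ls = lm.lag_scan(s, kind="RWD_PD", kin=kin)
        assert ls.best_shift_ms in ls.shifts_ms
        assert ls.n_pairs[ls.shifts_ms == ls.best_shift_ms] >= 3


class TestOnsets:
    def test_constant_rate_no_onsets(self):
        # perfectly regular spiking -> flat rate -> nothing crosses
        spikes = np.arange(0.0, 100.0, 0.1)
        o = lm.detect_firing_onsets(spikes, 0.0, 100.0)
        assert o.times.size == 0

    def test_sparse_unit_flagged_excluded(self):
        o = lm.detect_firing_onsets(np.array([5.0, 50.0]), 0.0, 100.0)
        assert o.excluded and o.threshold <= 4.0

    def test_rate_bump_onsets_located(self, rng):
        # 2 Hz background with 20 Hz bursts at known times
        bursts = np.arange(20.0, 200.0, 20.0)
        lam = lambda t: 2.0 + 18.0 * np.any(
            (t[:, None] >= bursts) & (t[:, None] < bursts + 0.5), axis=1)
        n = rng.poisson(20.0 * 200)
        cand = np.sort(rng.uniform(0, 200, n))
        spikes = cand[rng.uniform(0, 1, n) < lam(cand) / 20.0]
        o = lm.detect_firing_onsets(spikes, 0.0, 200.0)
        assert not o.excluded
        # one onset near the start of each burst
        for b in bursts:
            close = np.abs(o.times - b) < 0.15
            assert close.any()

    def test_constant_speed_no_accel_onsets(self):
        kin = lm.KinematicsParams(bump_amplitude=0.0, speed_noise_sd=0.0,
                                  rest_speed=30.0)
        traj = lm.generate_trajectory(["L"] * 3, lm.MazeConfig(), kin,
                                      np.random.default_rng(0))
        ks = lm.compute_kinematics(traj.tracking)
        o = lm.detect_accel_onsets(ks)
        assert o.times.size == 0

    def test_accel_onsets_in_bump_rise(self):
        # straight-line trajectory built from the generator's true speed
        # profile (the 2-D maze corners would add their own accel spikes)
        kin = lm.KinematicsParams(speed_noise_sd=0.0, rest_speed=30.0)
        traj = lm.generate_trajectory(["L"] * 10, lm.MazeConfig(), kin,
                                      np.random.default_rng(1))
        dt = np.diff(traj.times)
        x = np.concatenate(
            [[0.0], np.cumsum(0.5 * (traj.speed[:-1] + traj.speed[1:]) * dt)])
        ks = lm.compute_kinematics(
            lm.TrackingSeries(traj.times, x, np.zeros_like(x)))
        o = lm.detect_accel_onsets(ks)
        starts = np.sort(np.concatenate([
            [c[k] - kin.bump_lead for k in ("VC_ON_PD", "RWD_PD", "RTN_PD")]
            for c in traj.crossings]))
        assert o.times.size >= 0.8 * starts.size
        for t in o.times:
            d = t - starts[starts <= t + 1e-9]
            assert d.size and d[-1] <= kin.bump_duration + 0.1

    def test_onset_count_monotone_in_percentile(self, coupled_session):
        s, kin = coupled_session
        counts = [lm.detect_accel_onsets(kin, percentile=p).times.size
                  for p in (97.5, 95.0, 90.0)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_interpolated_crossing_times(self):
        t = np.arange(5.0)
        v = np.array([0.0, 0.0, 2.0, 0.0, 0.0])
        (c,) = _upward_crossings(t, v, 1.0)
        assert c == pytest.approx(1.5)


class TestOnsetCrossCorr:
    def test_exact_shift_recovered(self):
        f = OnsetSet("firing", np.arange(10.0, 400.0, 7.0), 1.0, 95.0)
        a = OnsetSet("accel", f.times + 0.035, 1.0, 97.5)
        xc = lm.onset_lag_crosscorr(f, a)
        assert xc.mean_lag_ms == pytest.approx(35.0)
        assert xc.n_pairs == f.times.size

    def test_independent_streams_near_zero(self, rng):
        f = OnsetSet("firing", np.sort(rng.uniform(0, 2000, 400)), 1, 95)
        a = OnsetSet("accel", np.sort(rng.uniform(0, 2000, 400)), 1, 97.5)
        xc = lm.onset_lag_crosscorr(f, a)
        se = 500.0 / np.sqrt(3) / np.sqrt(xc.n_pairs)
        assert abs(xc.mean_lag_ms) < 3 * se

    def test_empty_result_flagged(self):
        f = OnsetSet("firing", np.array([10.0]), 1, 95)
        a = OnsetSet("accel", np.array([100.0]), 1, 97.5)
        xc = lm.onset_lag_crosscorr(f, a)
        assert xc.empty and np.isnan(xc.mean_lag_ms)

    def test_event_scope_restriction(self, coupled_session):
        s, _ = coupled_session
        f = OnsetSet("firing", np.linspace(0, s.tracking.times[-1], 300),
                     1, 95)
        ev = s.event_times("VC_ON_PD")
        near = lm.restrict_onsets_near_events(f, ev, 1.0)
        for t in near.times:
            assert np.min(np.abs(ev - t)) <= 1.0
        far = np.setdiff1d(f.times, near.times)
        for t in far[:20]:
            assert np.min(np.abs(ev - t)) > 1.0

    def test_sign_consistency_between_lag_estimators(self):
        cfg = lm.SimConfig(n_trials=80, seed=55, vc_on_gain=1.0,
                           vc_off_gain=1.0, reward_suppression=1.0,
                           accel_coupling=0.25, firing_lead_delta=0.1)
        s = lm.simulate_session(cfg)
        kin = lm.session_kinematics(s)
        ls = lm.lag_scan(s, kind="VC_ON_PD", kin=kin)
        fo = lm.detect_firing_onsets(
            s.spikes[0].times, 0.0, float(s.tracking.times[-1]))
        ao = lm.detect_accel_onsets(kin)
        xc = lm.onset_lag_crosscorr(fo, ao)
        assert ls.best_shift_ms > 0 and xc.mean_lag_ms > 0
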