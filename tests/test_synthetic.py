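"""Synthetic session generator: cue automaton, agent, kinematics, spikes."""

import numpy as np
import pytest
from scipy import stats

import lcmaze as lm


def max_run(seq):
    best = cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


def max_window8_same_side(seq):
    worst = 0
    for i in range(len(seq) - 7):
        w = seq[i : i + 8]
        worst = max(worst, w.count("L"), w.count("R"))
    return worst


def max_alternation_span(seq):
    best = cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a != b else 1
        best = max(best, cur)
    return best


class TestCueSequence:
    def test_single_trial(self, rng):
        assert lm.generate_cue_sequence(1, rng)[0] in ("L", "R")

    @pytest.mark.parametrize("seed", range(5))
    def test_all_three_constraints_hold(self, seed):
        rng = np.random.default_rng(seed)
        seq = lm.generate_cue_sequence(1000, rng)
        assert len(seq) == 1000
        assert max_run(seq) <= 2
        assert max_window8_same_side(seq) <= 5
        assert max_alternation_span(seq) <= 4

    def test_both_sides_used(self, rng):
        seq = lm.generate_cue_sequence(50, rng)
        assert {"L", "R"} == set(seq)


class TestBehavior:
    def test_perfect_agent_switches_at_trial_20(self, rng):
        cues = lm.generate_cue_sequence(60, rng)
        agent = lm.AgentParams(p_follow_rule=1.0)
        res = lm.simulate_behavior(cues, agent, rng)
        assert res.rule_change_trials[0] == 20
        assert res.correct[:20].all()

    def test_chance_agent_never_switches(self, rng):
        cues = lm.generate_cue_sequence(100, rng)
        agent = lm.AgentParams(p_follow_rule=0.0, side_bias=0.5)
        res = lm.simulate_behavior(cues, agent, rng)
        assert res.rule_change_trials == []
        assert 0.3 < res.correct.mean() < 0.7

    def test_switch_preceded_by_criterion_window(self, rng):
        cues = lm.generate_cue_sequence(300, rng)
        agent = lm.AgentParams(p_follow_rule=0.95, attended_rule_lag=5)
        res = lm.simulate_behavior(cues, agent, rng)
        assert res.rule_change_trials  # high-accuracy agent does switch
        for r in res.rule_change_trials:
            assert res.correct[r - 20 : r].sum() >= 18

    def test_lagged_agent_dips_after_switch(self, rng):
        cues = lm.generate_cue_sequence(300, rng)
        agent = lm.AgentParams(p_follow_rule=1.0, attended_rule_lag=10)
        res = lm.simulate_behavior(cues, agent, rng)
        r = res.rule_change_trials[0]
        # still following the old (VC) rule under the TURN rule: at chance
        assert res.correct[r : r + 10].mean() < 0.8

    def test_blocks_cover_all_trials(self, rng):
        cues = lm.generate_cue_sequence(200, rng)
        res = lm.simulate_behavior(
            cues, lm.AgentParams(p_follow_rule=0.95), rng)
        cursor = 0
        for b in res.blocks:
            assert b.start_trial == cursor
            cursor = b.end_trial + 1
        assert cursor == 200


class TestTrajectory:
    def test_zero_bump_constant_speed(self):
        kin = lm.KinematicsParams(bump_amplitude=0.0, speed_noise_sd=0.0,
                                  rest_speed=30.0)
        traj = lm.generate_trajectory(
            ["L", "R"], lm.MazeConfig(), kin, np.random.default_rng(0))
        assert np.allclose(traj.speed, 30.0)
        assert np.allclose(traj.accel, 0.0, atol=1e-9)

    def test_acceleration_rises_before_vc(self):
        kin = lm.KinematicsParams(speed_noise_sd=0.0)
        traj = lm.generate_trajectory(
            ["L"] * 20, lm.MazeConfig(), kin, np.random.default_rng(1))
        pre, far = [], []
        for c in traj.crossings:
            vc = c["VC_ON_PD"]
            sel1 = (traj.times >= vc - 1) & (traj.times < vc)
            sel2 = (traj.times >= vc - 2) & (traj.times < vc - 1)
            pre.append(traj.accel[sel1].mean())
            far.append(traj.accel[sel2].mean())
        assert np.mean(pre) > np.mean(far)

    def test_crossings_ordered_within_each_trial(self):
        traj = lm.generate_trajectory(
            ["L", "R"] * 10, lm.MazeConfig(), lm.KinematicsParams(),
            np.random.default_rng(2))
        for c in traj.crossings:
            assert c["VC_ON_PD"] < c["RWD_PD"] < c["well"] < c["RTN_PD"]

    def test_crossing_times_consistent_with_tracking(self):
        maze = lm.MazeConfig()
        kin = lm.KinematicsParams(speed_noise_sd=0.0, tracking_noise_cm=0.0)
        traj = lm.generate_trajectory(
            ["L"] * 5, maze, kin, np.random.default_rng(3))
        # at the VC crossing the LED must be at the central-arm PD position:
        # path coordinate 70 -> (0, 50) in 2-D
        for c in traj.crossings:
            x = np.interp(c["VC_ON_PD"], traj.times, traj.tracking.x)
            y = np.interp(c["VC_ON_PD"], traj.times, traj.tracking.y)
            assert abs(x - 0.0) < 1.5 and abs(y - 50.0) < 1.5

    def test_negative_speed_parameters_rejected(self):
        with pytest.raises(ValueError, match="negative speed"):
            lm.KinematicsParams(bump_amplitude=-100.0)


@pytest.fixture
def neutral_cfg():
    return dict(vc_on_gain=1.0, vc_off_gain=1.0, reward_suppression=1.0,
                accel_coupling=0.0)


class TestSpikes:
    def test_homogeneous_rate_matches_baseline(self, neutral_cfg):
        cfg = lm.SimConfig(n_trials=60, seed=11, baseline_rate_hz=2.0,
                           **neutral_cfg)
        s = lm.simulate_session(cfg)
        t_end = s.tracking.times[-1]
        n = s.spikes[0].times.size
        se = np.sqrt(2.0 * t_end)
        assert abs(n - 2.0 * t_end) < 3 * se

    def test_vc_gain_doubles_window_rate(self, neutral_cfg):
        cfg_d = dict(neutral_cfg)
        cfg_d["vc_on_gain"] = 2.0
        cfg = lm.SimConfig(n_trials=150, seed=12, **cfg_d)
        s = lm.simulate_session(cfg)
        t = s.spikes[0].times
        vc = np.array([tr.vc_on_time for tr in s.trials])
        count = sum(
            np.searchsorted(t, v) - np.searchsorted(t, v - 0.5) for v in vc)
        expected = 2.0 * 2.0 * 0.5 * len(vc)
        assert abs(count - expected) < 3 * np.sqrt(expected)
        # reward-site window stays at baseline
        rwd = np.array([tr.rwd_pd_time for tr in s.trials])
        c2 = sum(
            np.searchsorted(t, r + 2) - np.searchsorted(t, r + 1) for r in rwd)
        assert abs(c2 - 2.0 * len(vc)) < 3 * np.sqrt(2.0 * len(vc))

    def test_reward_suppression_scales_rate(self, neutral_cfg):
        cfg_d = dict(neutral_cfg)
        cfg_d["reward_suppression"] = 0.4
        cfg = lm.SimConfig(n_trials=150, seed=13, **cfg_d)
        s = lm.simulate_session(cfg)
        t = s.spikes[0].times
        rwd = np.array([tr.rwd_pd_time for tr in s.trials])
        count = sum(
            np.searchsorted(t, r + 2) - np.searchsorted(t, r + 1) for r in rwd)
        expected = 0.4 * 2.0 * len(rwd)
        assert abs(count - expected) < 3 * np.sqrt(expected)

    def test_piecewise_constant_counts_are_poisson(self, rng):
        # 500 replicates of the 100 ms laser window at 10 Hz: counts must
        # follow Poisson(1.0) (chi-square GOF at alpha = 0.01)
        counts = []
        for _ in range(500):
            train, pulses = lm.simulate_opto_tagging(2.0, 5.0, 2, rng)
            p0 = pulses[0].time
            counts.append(
                int(np.searchsorted(train.times, p0 + 0.1)
                    - np.searchsorted(train.times, p0)))
        counts = np.asarray(counts)
        kmax = 4
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), 1.0)
        probs = np.concatenate([pmf, [1 - pmf.sum()]])
        res = stats.chisquare(obs, 500 * probs)
        assert res.pvalue > 0.01


class TestSession:
    def test_same_seed_identical_sessions(self):
        cfg = lm.SimConfig(n_trials=15, seed=21)
        assert lm.simulate_session(cfg) == lm.simulate_session(cfg)

    def test_trial_count(self):
        s = lm.simulate_session(lm.SimConfig(n_trials=60, seed=22))
        assert s.n_trials == 60

    def test_event_times_match_tracking_crossings(self):
        cfg = lm.SimConfig(
            n_trials=10, seed=23,
            kin=lm.KinematicsParams(tracking_noise_cm=0.0))
        s = lm.simulate_session(cfg)
        dt = s.maze.video_dt
        # rebuild path coordinate from tracking and check PD positions
        for tr in s.trials:
            i = np.searchsorted(s.tracking.times, tr.vc_on_time)
            assert s.tracking.times[i] - tr.vc_on_time < 2 * dt

    def test_laser_block_pulses(self):
        cfg = lm.SimConfig(n_trials=5, seed=24, laser_n_pulses=100,
                           laser_gain=5.0)
        s = lm.simulate_session(cfg)
        pulses = s.event_times("LASER_PULSE")
        assert pulses.size == 100
        assert np.allclose(np.diff(pulses), 0.5)  # 2 Hz stimulation
        res = lm.classify_opto_unit(
            s.spikes[0], list(pulses),
            baseline_window=(0.0, pulses[0] - 10.0))
        assert res.status == "entrained"


class TestOptoTagging:
    def test_entrained_gain5(self, rng):
        train, pulses = lm.simulate_opto_tagging(2.0, 5.0, 100, rng, t0=50.0)
        base = np.sort(rng.uniform(0, 40, 80))  # 2 Hz baseline segment
        full = lm.SpikeTrain("u", np.unique(
            np.concatenate([base, train.times])))
        res = lm.classify_opto_unit(full, pulses, baseline_window=(0, 40))
        assert res.status == "entrained"

    def test_gain1_not_entrained(self, rng):
        train, pulses = lm.simulate_opto_tagging(2.0, 1.0, 200, rng, t0=50.0)
        base = np.sort(rng.uniform(0, 40, 80))
        full = lm.SpikeTrain("u", np.unique(
            np.concatenate([base, train.times])))
        res = lm.classify_opto_unit(full, pulses, baseline_window=(0, 40))
        assert res.status == "not_entrained"

    def test_pulse_spacing_half_second(self, rng):
        _, pulses = lm.simulate_opto_tagging(2.0, 5.0, 20, rng)
        times = [p.time for p in pulses]
        assert np.allclose(np.diff(times), 0.5)
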