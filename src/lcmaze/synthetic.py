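"""Synthetic T-maze session generator.

The study's recordings are not public, so this module generates complete
sessions carrying the statistical structure the analysis pipeline assumes:

* a constrained pseudorandom cue sequence (no side lit more than twice in a
  row, no two-trial alternation repeated more than twice, at most five
  same-side cues in any eight successive trials);
* a behaving agent whose choices follow the currently *attended* rule with
  some probability, with a configurable lag before it notices rule changes;
  the rule switches automatically when the moving-window criterion of at
  least 18 correct out of the last 20 trials is met;
* maze-path kinematics at ~30 Hz: cruise locomotion with a smooth
  acceleration bump beginning a fixed lead before each photodetector
  crossing, a dwell at the reward well, a pause in the start area, and an
  Ornstein-Uhlenbeck speed-fluctuation term (rats do not run at constant
  speed, and this trial-to-trial acceleration variability is what gives the
  lag analyses their timing resolution);
* locus-coeruleus-like spikes from an inhomogeneous Poisson process

  .. math::

     \\lambda(t) = b \\cdot g_{ev}(t) \\cdot s_{rwd}(t)
                   + g_a \\cdot \\max(0, a(t + \\delta))

  with multiplicative event gains before the VC-onset and return-arm
  photodetector crossings, multiplicative suppression at the reward site,
  and additive coupling to positive acceleration at a configurable firing
  *lead* ``delta`` (firing precedes acceleration by ``delta``), sampled
  exactly by thinning.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .session import (
    Block,
    MazeConfig,
    Session,
    SpikeTrain,
    TaskEvent,
    TrackingSeries,
    build_trials,
    other_side,
    rule_is_rewarded,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgentParams:
    """Behavioral agent: follows its attended rule with probability
    ``p_follow_rule``; updates the attended rule ``attended_rule_lag`` trials
    after a rule change; when guessing, picks ``preferred_side`` with
    probability ``side_bias``."""

    p_follow_rule: float = 0.9
    attended_rule_lag: int = 3
    side_bias: float = 0.5
    preferred_side: str = "L"

    def __post_init__(self):
        if not 0 <= self.p_follow_rule <= 1:
            raise ValueError("p_follow_rule must be in [0, 1]")
        if not 0 <= self.side_bias <= 1:
            raise ValueError("side_bias must be in [0, 1]")
        if self.attended_rule_lag < 0:
            raise ValueError("attended_rule_lag must be >= 0")


@dataclass(frozen=True)
class KinematicsParams:
    """Speed-profile parameters (cm, s).

    The acceleration bump before each photodetector crossing is the rising
    half of a raised-cosine speed bump: positive acceleration of peak
    ``bump_amplitude`` lasting ``bump_duration``, beginning ``bump_lead``
    before the crossing, followed by the symmetric deceleration.
    ``speed_noise_sd``/``speed_noise_tau`` parameterise an
    Ornstein-Uhlenbeck fluctuation around the profile (sd at cruise speed;
    scaled down proportionally when the base speed is low, e.g. at the
    reward well).
    """

    cruise_speed: float = 30.0
    bump_amplitude: float = 40.0
    bump_duration: float = 0.8
    bump_lead: float = 0.8
    speed_noise_sd: float = 3.0
    speed_noise_tau: float = 0.3
    dwell_s: float = 2.5
    pause_s: float = 1.5
    ramp_s: float = 0.4
    rest_speed: float = 1.0
    tracking_noise_cm: float = 0.0

    def __post_init__(self):
        if self.cruise_speed <= 0 or self.bump_duration <= 0:
            raise ValueError("cruise speed and bump duration must be > 0")
        if self.bump_lead < 0 or self.ramp_s <= 0 or self.rest_speed <= 0:
            raise ValueError("invalid kinematics parameters")
        # raised-cosine bump depth for negative amplitudes
        dv = 2.0 * self.bump_amplitude * self.bump_duration / math.pi
        if self.cruise_speed + min(0.0, dv) <= 0:
            raise ValueError("bump parameters imply negative speed")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a synthetic session.

    Defaults are the study conditions: ~2 Hz tonic locus coeruleus firing,
    event gains matching the reported VC-onset (1.5) and VC-OFF (1.4)
    response ratios, reward-site suppression to 0.44 of baseline, and firing
    leading acceleration by 35 ms.  ``post_shift_vc_gain`` multiplies the
    baseline over the 0.5 s *after* VC onset on trials following the first
    rule change (the novelty response to the now-irrelevant cue); 1
    disables it.
    """

    n_trials: int = 80
    seed: int = 0
    baseline_rate_hz: float = 2.0
    vc_on_gain: float = 1.5
    vc_off_gain: float = 1.4
    event_gain_window: tuple = (-1.0, 0.0)
    accel_coupling: float = 0.05  # Hz per (cm/s^2), positive accel only
    firing_lead_delta: float = 0.035  # s; firing precedes acceleration
    reward_suppression: float = 0.44
    reward_supp_window: tuple = (1.0, 2.0)
    post_shift_vc_gain: float = 1.0
    n_units: int = 1
    agent: AgentParams = field(default_factory=AgentParams)
    kin: KinematicsParams = field(default_factory=KinematicsParams)
    maze: MazeConfig = field(default_factory=MazeConfig)
    initial_rule: str = "VC"
    turn_side: str = "R"
    criterion: tuple = (18, 20)
    max_switches: int | None = None
    laser_n_pulses: int = 0
    laser_gain: float = 5.0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.baseline_rate_hz < 0 or self.accel_coupling < 0:
            raise ValueError("rates and gains must be >= 0")
        if self.vc_on_gain < 0 or self.vc_off_gain < 0:
            raise ValueError("event gains must be >= 0")
        if not 0 < self.reward_suppression <= 1:
            raise ValueError("reward suppression factor must be in (0, 1]")
        k, w = self.criterion
        if not 0 < k <= w:
            raise ValueError("criterion must be (k, window) with 0 < k <= w")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maze"] = self.maze.to_dict()
        for key in ("event_gain_window", "reward_supp_window", "criterion"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["agent"] = AgentParams(**d.get("agent", {}))
        d["kin"] = KinematicsParams(**d.get("kin", {}))
        d["maze"] = MazeConfig.from_dict(d["maze"]) if "maze" in d else MazeConfig()
        for key in ("event_gain_window", "reward_supp_window", "criterion"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# pseudorandom cue sequence

def _prefix_ok(seq: list) -> bool:
    """Check the three printed constraints on the suffix of a prefix.

    Each constraint is local to the last <= 8 trials, so validating every
    extension keeps whole sequences valid.
    """
    n = len(seq)
    # (i) no side lit on more than 2 consecutive trials
    if n >= 3 and seq[-1] == seq[-2] == seq[-3]:
        return False
    # (ii) a two-trial alternation repeats at most twice: a strict
    # alternation may span at most 4 trials
    if n >= 5 and all(seq[-i] != seq[-i - 1] for i in range(1, 5)):
        return False
    # (iii) at most 5 same-side cues in any 8 successive trials
    if n >= 8:
        window = seq[-8:]
        c = window.count("L")
        if max(c, 8 - c) > 5:
            return False
    return True


def generate_cue_sequence(n_trials: int, rng) -> list:
    """Constrained pseudorandom L/R cue sequence.

    Backtracking search with randomised branch order; terminates for any
    ``n_trials`` (the constraint set is satisfiable for all lengths).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seq: list = []
    options: list = []  # per-depth untried sides
    while len(seq) < n_trials:
        if len(options) == len(seq):
            opts = ["L", "R"]
            rng.shuffle(opts)
            options.append(opts)
        placed = False
        while options[len(seq)]:
            side = options[len(seq)].pop()
            seq.append(side)
            if _prefix_ok(seq):
                placed = True
                break
            seq.pop()
        if not placed:
            options.pop()
            if not seq:
                raise RuntimeError("cue sequence search exhausted")  # pragma: no cover
            seq.pop()
    return seq


# ---------------------------------------------------------------------------
# behavior

@dataclass
class BehaviorResult:
    choices: list
    correct: np.ndarray
    rule_per_trial: list
    rule_change_trials: list  # first trial index under each new rule
    strategy_change_trials: list  # first trial with the updated attended rule
    blocks: list


def simulate_behavior(
    cues: list,
    agent: AgentParams,
    rng,
    initial_rule: str = "VC",
    turn_side: str = "R",
    criterion: tuple = (18, 20),
    max_switches: int | None = None,
) -> BehaviorResult:
    """Run the task automaton and agent over a cue sequence.

    The rule alternates between ``initial_rule`` and the turn rule (or back)
    each time the criterion -- at least ``criterion[0]`` correct of the last
    ``criterion[1]`` trials, counting only trials since the previous switch
    -- is met; the switch takes effect on the next trial.  If the criterion
    is never reached no switch is emitted (logged).
    """
    k_need, window = criterion
    turn_rule = f"TURN_{turn_side}"
    rules_cycle = (initial_rule, turn_rule if initial_rule == "VC" else "VC")
    n = len(cues)
    rule = initial_rule
    attended = initial_rule
    pending_attend: list = []  # (trial index at which attended updates, rule)
    choices, rule_per_trial = [], []
    correct = np.zeros(n, dtype=bool)
    rule_changes: list = []
    strategy_changes: list = []
    since_switch = 0
    n_switches = 0

    def prescribed(r: str, cue: str) -> str:
        return cue if r == "VC" else r[-1]

    for i in range(n):
        while pending_attend and pending_attend[0][0] == i:
            _, attended = pending_attend.pop(0)
            strategy_changes.append(i)
        rule_per_trial.append(rule)
        if rng.random() < agent.p_follow_rule:
            choice = prescribed(attended, cues[i])
        else:
            choice = (
                agent.preferred_side
                if rng.random() < agent.side_bias
                else other_side(agent.preferred_side)
            )
        choices.append(choice)
        correct[i] = rule_is_rewarded(rule, cues[i], choice)
        since_switch += 1
        if (
            since_switch >= window
            and int(correct[i - window + 1 : i + 1].sum()) >= k_need
            and (max_switches is None or n_switches < max_switches)
            and i + 1 < n
        ):
            rule = rules_cycle[1] if rule == rules_cycle[0] else rules_cycle[0]
            rule_changes.append(i + 1)
            pending_attend.append((i + 1 + agent.attended_rule_lag, rule))
            since_switch = 0
            n_switches += 1
    if not rule_changes:
        log.info("criterion never reached in %d trials; no rule switch", n)

    bounds = sorted({0, n, *rule_changes, *strategy_changes})
    blocks = []
    att = initial_rule
    att_changes = dict(
        zip(strategy_changes, [r for _, r in _attend_history(
            initial_rule, rule_changes, rule_per_trial)])
    )
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a in att_changes:
            att = att_changes[a]
        blocks.append(Block(a, b - 1, f"{rule_per_trial[a]}|att:{att}"))
    return BehaviorResult(
        choices, correct, rule_per_trial, rule_changes, strategy_changes,
        blocks,
    )


def _attend_history(initial_rule, rule_changes, rule_per_trial):
    """Attended-rule value adopted at each strategy change, in order."""
    return [(t, rule_per_trial[min(t, len(rule_per_trial) - 1)])
            for t in rule_changes]


# ---------------------------------------------------------------------------
# trajectory

# canonical 2-D waypoints of one lap (left choice); x mirrored for right
_WAYPOINTS_L = np.array(
    [
        (0.0, -20.0),  # start-area entry
        (0.0, 0.0),    # central-arm base
        (0.0, 100.0),  # T junction
        (-50.0, 100.0),  # reward well
        (-50.0, -20.0),  # return-arm corner
        (0.0, -20.0),  # back at start
    ]
)


def _path_to_xy(s: np.ndarray, side: str) -> tuple:
    wp = _WAYPOINTS_L.copy()
    if side == "R":
        wp[:, 0] = -wp[:, 0]
    seg = np.hypot(*np.diff(wp, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.clip(s, 0.0, cum[-1] - 1e-9)
    return np.interp(s, cum, wp[:, 0]), np.interp(s, cum, wp[:, 1])


def _ramp_up(t: np.ndarray, t0: float, ramp: float) -> np.ndarray:
    u = np.clip((t - t0) / ramp, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


@dataclass
class TrajectoryResult:
    """Generated session kinematics: tracking output plus the underlying
    true speed/acceleration on the same uniform grid, and the exact
    (sub-frame) photodetector crossing times per trial."""

    tracking: TrackingSeries
    times: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    crossings: list  # per trial: dict kind -> time (plus "well")
    trial_starts: np.ndarray


def _simulate_trial(kin: KinematicsParams, maze: MazeConfig, ou_source,
                    pd_pos: dict, well_pos: float):
    """One lap's speed profile on a uniform grid, with photodetector
    crossing times made self-consistent by fixed-point iteration (the
    acceleration bumps are anchored to the crossing times they modify)."""
    dt = maze.video_dt
    L = maze.path_length
    c = kin.cruise_speed
    base_travel = kin.pause_s + L / c + kin.dwell_s + 3 * kin.ramp_s
    n = int(math.ceil(base_travel * 1.8 / dt)) + 8
    t = np.arange(n) * dt
    ou = ou_source(n)
    dv = 2.0 * kin.bump_amplitude * kin.bump_duration / math.pi
    T_bump = 2.0 * kin.bump_duration

    # initial guesses at constant cruise speed
    def naive(p):
        return kin.pause_s + 0.5 * kin.ramp_s + p / c

    anchors = {k: naive(p) for k, p in pd_pos.items()}
    t_dwell = naive(well_pos)
    t_end = naive(L) + kin.dwell_s + kin.ramp_s

    for _ in range(4):
        env = _ramp_up(t, kin.pause_s, kin.ramp_s)
        g_dwell = _ramp_up(t, t_dwell, kin.ramp_s) * (
            1.0 - _ramp_up(t, t_dwell + kin.ramp_s + kin.dwell_s, kin.ramp_s)
        )
        g_end = _ramp_up(t, t_end - kin.ramp_s, kin.ramp_s)
        v_base = kin.rest_speed + (c - kin.rest_speed) * env * (
            1.0 - g_dwell) * (1.0 - g_end)
        v = v_base + (v_base / c) * ou
        for a in anchors.values():
            t0 = a - kin.bump_lead
            tau = (t - t0) / T_bump
            inside = (tau >= 0) & (tau < 1)
            v[inside] += dv * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau[inside]))
        v = np.maximum(v, 0.25)
        # trapezoidal integration: v[i] is the instantaneous speed at t[i],
        # so tracking-derived (per-frame) speed is the two-sample mean and
        # tracking-derived acceleration matches np.gradient(v) exactly
        s = np.concatenate([[0.0], np.cumsum(0.5 * (v[:-1] + v[1:]) * dt)])
        if s[-1] < L:  # grid too short (slow noise draw); extend
            n += int(math.ceil(2.0 / dt))
            t = np.arange(n) * dt
            ou = ou_source(n)
            continue

        def crossing(p):
            i = int(np.searchsorted(s, p))
            return t[i - 1] + (p - s[i - 1]) / v[i - 1]

        new_anchors = {k: crossing(p) for k, p in pd_pos.items()}
        new_dwell = crossing(well_pos)
        new_end = crossing(L - 1e-9)
        done = (
            abs(new_dwell - t_dwell) < dt / 4
            and all(abs(new_anchors[k] - anchors[k]) < dt / 4 for k in anchors)
        )
        anchors, t_dwell, t_end = new_anchors, new_dwell, new_end
        if done:
            break
    n_frames = int(math.ceil(t_end / dt))
    return t[:n_frames], v[:n_frames], s[:n_frames], anchors, t_dwell


def generate_trajectory(choices: list, maze: MazeConfig,
                        kin: KinematicsParams, rng) -> TrajectoryResult:
    """30 Hz maze-path kinematics for a sequence of trials.

    Returns tracking (2-D positions, optionally jittered), the true speed
    and acceleration on the same grid, and per-trial crossing times that are
    exactly consistent with the integrated trajectory.
    """
    dt = maze.video_dt
    pd_pos = dict(maze.pd_positions)
    well_pos = (
        maze.start_runway + maze.central_arm_length + maze.reward_arm_length
    )
    alpha = math.exp(-dt / kin.speed_noise_tau)
    sigma_step = kin.speed_noise_sd * math.sqrt(1.0 - alpha**2)
    ou_state = [0.0]

    def ou_source(n):
        out = np.empty(n)
        x = ou_state[0]
        steps = rng.normal(0.0, sigma_step, n)
        for i in range(n):
            x = alpha * x + steps[i]
            out[i] = x
        ou_state[0] = x
        return out

    times, speeds, paths, crossings, starts = [], [], [], [], []
    offset = 0.0
    for choice in choices:
        t, v, s, anchors, t_dwell = _simulate_trial(
            kin, maze, ou_source, pd_pos, well_pos
        )
        times.append(t + offset)
        speeds.append(v)
        paths.append((s, choice))
        crossings.append(
            {k: a + offset for k, a in anchors.items()}
            | {"well": t_dwell + offset}
        )
        starts.append(offset)
        offset += t.size * dt
    t_all = np.concatenate(times)
    v_all = np.concatenate(speeds)
    a_all = np.gradient(v_all, dt)
    xs, ys = [], []
    for s, choice in paths:
        x, y = _path_to_xy(s, choice)
        xs.append(x)
        ys.append(y)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    if kin.tracking_noise_cm > 0:
        x_all = x_all + rng.normal(0.0, kin.tracking_noise_cm, x_all.size)
        y_all = y_all + rng.normal(0.0, kin.tracking_noise_cm, y_all.size)
    tracking = TrackingSeries(t_all, x_all, y_all)
    return TrajectoryResult(
        tracking, t_all, v_all, a_all, crossings, np.asarray(starts)
    )


# ---------------------------------------------------------------------------
# spikes

def _window_factor(t: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                   factors: np.ndarray) -> np.ndarray:
    """Multiplicative factor from non-overlapping half-open windows."""
    out = np.ones(t.size)
    if starts.size == 0:
        return out
    idx = np.searchsorted(starts, t, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(t.size, dtype=bool)
    inside[ok] = t[ok] < ends[idx[ok]]
    out[inside] = factors[idx[inside]]
    return out


def generate_spikes(
    cfg: SimConfig,
    traj: TrajectoryResult,
    rng,
    post_shift_time: float | None = None,
    t_end: float | None = None,
) -> np.ndarray:
    """Spike times from the inhomogeneous Poisson intensity by thinning.

    ``lambda(t) = b * event_gain(t) * reward_supp(t)
    + g_a * max(0, a(t + delta))`` where the event gain multiplies the
    baseline over ``event_gain_window`` before each VC-onset / return-arm
    crossing (the VC gain additionally multiplied by ``post_shift_vc_gain``
    after ``post_shift_time``), and the suppression factor applies over
    ``reward_supp_window`` after each reward-arm crossing.
    """
    if t_end is None:
        t_end = float(traj.times[-1]) + cfg.maze.video_dt
    w0, w1 = cfg.event_gain_window
    s0, s1 = cfg.reward_supp_window
    vc = np.array([c["VC_ON_PD"] for c in traj.crossings])
    rtn = np.array([c["RTN_PD"] for c in traj.crossings])
    rwd = np.array([c["RWD_PD"] for c in traj.crossings])
    gain_starts = np.concatenate([vc + w0, rtn + w0])
    gain_ends = np.concatenate([vc + w1, rtn + w1])
    gain_vals = np.concatenate([
        np.full(vc.size, cfg.vc_on_gain),
        np.full(rtn.size, cfg.vc_off_gain),
    ])
    if post_shift_time is not None and cfg.post_shift_vc_gain != 1.0:
        # novelty response to the now-irrelevant cue: the 0.5 s after VC
        # onset, on trials after the first rule shift
        vc_post = vc[vc >= post_shift_time]
        gain_starts = np.concatenate([gain_starts, vc_post])
        gain_ends = np.concatenate([gain_ends, vc_post + 0.5])
        gain_vals = np.concatenate(
            [gain_vals, np.full(vc_post.size, cfg.post_shift_vc_gain)]
        )
    order = np.argsort(gain_starts)
    gain_starts, gain_ends, gain_vals = (
        gain_starts[order], gain_ends[order], gain_vals[order]
    )
    supp_starts, supp_ends = rwd + s0, rwd + s1
    supp_vals = np.full(rwd.size, cfg.reward_suppression)

    a_pos_max = max(0.0, float(traj.accel.max())) if traj.accel.size else 0.0
    lam_max = (
        cfg.baseline_rate_hz
        * max(1.0, cfg.vc_on_gain)
        * max(1.0, cfg.vc_off_gain)
        * max(1.0, cfg.post_shift_vc_gain)
        + cfg.accel_coupling * a_pos_max
    )
    if lam_max <= 0:
        return np.array([])
    n_cand = rng.poisson(lam_max * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, n_cand))
    lam = cfg.baseline_rate_hz * _window_factor(
        cand, gain_starts, gain_ends, gain_vals
    ) * _window_factor(cand, supp_starts, supp_ends, supp_vals)
    if cfg.accel_coupling > 0:
        a_shift = np.interp(
            cand + cfg.firing_lead_delta, traj.times, traj.accel,
            left=0.0, right=0.0,
        )
        lam = lam + cfg.accel_coupling * np.maximum(a_shift, 0.0)
    if np.any(lam > lam_max * (1 + 1e-9)):
        raise RuntimeError(
            "intensity exceeded the thinning envelope; inconsistent config"
        )
    keep = rng.uniform(0.0, 1.0, n_cand) < lam / lam_max
    return cand[keep]


def simulate_opto_tagging(
    baseline_rate: float,
    entrainment_gain: float,
    n_pulses: int,
    rng,
    pulse_rate_hz: float = 2.0,
    pulse_dur_s: float = 0.1,
    t0: float = 0.0,
) -> tuple:
    """Laser-pulse train (2 Hz, 100 ms by default) plus a spike train firing
    at ``entrainment_gain x baseline`` within pulses and at baseline
    elsewhere.  Returns ``(SpikeTrain, [TaskEvent, ...])``."""
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    period = 1.0 / pulse_rate_hz
    pulses = t0 + period * np.arange(n_pulses)
    t_end = pulses[-1] + period
    lam_max = baseline_rate * max(1.0, entrainment_gain)
    spikes = np.array([])
    if lam_max > 0:
        n_cand = rng.poisson(lam_max * (t_end - t0))
        cand = np.sort(rng.uniform(t0, t_end, n_cand))
        rel = (cand - t0) % period
        lam = np.where(
            rel < pulse_dur_s,
            baseline_rate * entrainment_gain,
            baseline_rate,
        )
        keep = rng.uniform(0.0, 1.0, n_cand) < lam / lam_max
        spikes = cand[keep]
    events = [TaskEvent(float(p), "LASER_PULSE") for p in pulses]
    train = SpikeTrain("opto", spikes, waveform_ms=0.8)
    return train, events


# ---------------------------------------------------------------------------
# full session

def simulate_session(cfg: SimConfig) -> Session:
    """Generate a complete, validated synthetic :class:`Session`."""
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(6)
    r_cue, r_beh, r_traj = (np.random.default_rng(s) for s in children[:3])
    spike_seeds = children[3].spawn(cfg.n_units)
    laser_seeds = children[4].spawn(max(cfg.n_units, 1))
    cues = generate_cue_sequence(cfg.n_trials, r_cue)
    beh = simulate_behavior(
        cues, cfg.agent, r_beh,
        initial_rule=cfg.initial_rule, turn_side=cfg.turn_side,
        criterion=cfg.criterion, max_switches=cfg.max_switches,
    )
    traj = generate_trajectory(beh.choices, cfg.maze, cfg.kin, r_traj)

    events = []
    for i, (cue, choice) in enumerate(zip(cues, beh.choices)):
        c = traj.crossings[i]
        events.append(TaskEvent(c["VC_ON_PD"], "VC_ON_PD", cue))
        events.append(TaskEvent(c["RWD_PD"], "RWD_PD", choice))
        if beh.correct[i]:
            events.append(TaskEvent(c["RWD_PD"] + 0.05, "REWARD", choice))
        events.append(TaskEvent(c["RTN_PD"], "RTN_PD", choice))
    for r in beh.rule_change_trials:
        tt = 0.5 * (
            traj.crossings[r - 1]["RTN_PD"] + traj.crossings[r]["VC_ON_PD"]
        )
        events.append(TaskEvent(tt, "RULE_CHANGE", payload=beh.rule_per_trial[r]))
    for sctrial in beh.strategy_change_trials:
        tt = 0.5 * (
            traj.crossings[sctrial - 1]["RTN_PD"]
            + traj.crossings[sctrial]["VC_ON_PD"]
        ) + 1e-3  # after a coincident rule change, never identical times
        events.append(TaskEvent(tt, "STRATEGY_CHANGE"))

    post_shift_time = None
    if beh.rule_change_trials:
        r = beh.rule_change_trials[0]
        post_shift_time = 0.5 * (
            traj.crossings[r - 1]["RTN_PD"] + traj.crossings[r]["VC_ON_PD"]
        )
    t_end = float(traj.times[-1]) + cfg.maze.video_dt

    spikes = []
    for u in range(cfg.n_units):
        r_u = np.random.default_rng(spike_seeds[u])
        st = generate_spikes(cfg, traj, r_u, post_shift_time, t_end)
        waveform = float(r_u.uniform(0.65, 1.1))
        spikes.append(SpikeTrain(f"u{u}", st, waveform_ms=round(waveform, 3)))

    if cfg.laser_n_pulses > 0:
        laser_t0 = t_end + 5.0
        for u, tr in enumerate(spikes):
            opto, pulse_events = simulate_opto_tagging(
                cfg.baseline_rate_hz, cfg.laser_gain, cfg.laser_n_pulses,
                np.random.default_rng(laser_seeds[u]),
                t0=laser_t0,
            )
            spikes[u] = SpikeTrain(
                tr.unit_id,
                np.concatenate([tr.times, opto.times]),
                tr.waveform_ms,
                tr.opto_status,
            )
        events.extend(pulse_events)

    events.sort(key=lambda e: e.time)
    trials = build_trials(events, cfg.initial_rule)
    session = Session(
        maze=cfg.maze,
        spikes=spikes,
        tracking=traj.tracking,
        events=events,
        trials=trials,
        blocks=beh.blocks,
        meta={"rat_id": "SYN", "seed": cfg.seed, "config": cfg.to_dict()},
        initial_rule=cfg.initial_rule,
    )
    session.validate()
    return session
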