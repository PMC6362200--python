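"""Shared fixtures: compact hand-built sessions with controllable firing,
independent of the full simulator, for unit-testing the analyses."""

import numpy as np
import pytest

from lcmaze import (
    Block,
    MazeConfig,
    Session,
    SpikeTrain,
    TaskEvent,
    TrackingSeries,
    build_trials,
)


def poisson_train(rng, rate_fn, t_end, lam_max, unit_id="u0", waveform=0.9):
    """Inhomogeneous Poisson spikes by thinning; ``rate_fn`` vectorised."""
    n = rng.poisson(lam_max * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, n))
    lam = rate_fn(cand)
    keep = rng.uniform(0, 1, n) < lam / lam_max
    return SpikeTrain(unit_id, cand[keep], waveform_ms=waveform)


def manual_session(
    n_trials,
    rng=None,
    iti=14.0,
    rate_fn=None,
    lam_max=None,
    rule_change_trial=None,
    spike_times=None,
    tracking=None,
):
    """A rigid-schedule session: trial i has VC onset at ``5 + i*iti``,
    reward-arm PD 2.5 s later, return-arm PD 7 s after VC onset.  The rat
    always chooses L; an optional rule change switches VC -> TURN_L (so
    every trial stays rewarded and consistent)."""
    events = []
    for i in range(n_trials):
        vc = 5.0 + i * iti
        events.append(TaskEvent(vc, "VC_ON_PD", "L"))
        events.append(TaskEvent(vc + 2.5, "RWD_PD", "L"))
        events.append(TaskEvent(vc + 2.55, "REWARD", "L"))
        events.append(TaskEvent(vc + 7.0, "RTN_PD", "L"))
    if rule_change_trial is not None:
        tt = 5.0 + rule_change_trial * iti - 1.0
        events.append(TaskEvent(tt, "RULE_CHANGE", payload="TURN_L"))
        blocks = [
            Block(0, rule_change_trial - 1, "VC"),
            Block(rule_change_trial, n_trials - 1, "TURN_L"),
        ]
    else:
        blocks = [Block(0, n_trials - 1, "VC")]
    events.sort(key=lambda e: e.time)
    t_end = 5.0 + n_trials * iti
    if spike_times is not None:
        spikes = [SpikeTrain("u0", np.asarray(spike_times, float),
                             waveform_ms=0.9)]
    elif rate_fn is not None:
        spikes = [poisson_train(rng, rate_fn, t_end, lam_max)]
    else:
        spikes = [SpikeTrain("u0", np.array([]), waveform_ms=0.9)]
    session = Session(
        maze=MazeConfig(),
        spikes=spikes,
        tracking=tracking,
        events=events,
        trials=build_trials(events),
        blocks=blocks,
        meta={"rat_id": "MANUAL"},
    )
    session.validate()
    return session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
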