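"""Typed data model for a T-maze locus coeruleus recording session.

A session bundles spike trains, head-LED tracking, the timestamped task-event
log, the trial/block structure derived from it, and unit metadata.  Sessions
live on disk as a plain-text directory bundle (CSV + JSON) documented in
:func:`write_session`.

Conventions
-----------
* Time is seconds from session start.
* All analysis windows are half-open ``[a, b)``.
* Sides are ``"L"``/``"R"`` as seen from the start area, ``"NA"`` for events
  that are not arm specific.
* Rules are ``"VC"`` (follow the lit screen) or ``"TURN_L"``/``"TURN_R"``
  (always choose that arm).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EVENT_KINDS = (
    "VC_ON_PD",
    "RWD_PD",
    "RTN_PD",
    "REWARD",
    "RULE_CHANGE",
    "STRATEGY_CHANGE",
    "LASER_PULSE",
)
#: event kinds that carry an arm side
ARM_EVENT_KINDS = ("VC_ON_PD", "RWD_PD", "RTN_PD", "REWARD")
SIDES = ("L", "R", "NA")
RULES = ("VC", "TURN_L", "TURN_R")


class SessionValidationError(ValueError):
    """An invariant of the session data model is violated."""


class SessionLoadError(IOError):
    """A session bundle on disk is missing a file or is unreadable."""


def other_side(side: str) -> str:
    return "R" if side == "L" else "L"


def rule_is_rewarded(rule: str, cue_side: str, chosen_side: str) -> bool:
    """Reward contingency: which arm pays off under ``rule``.

    ``VC``: the arm in front of the lit screen.  ``TURN_L``/``TURN_R``: the
    fixed arm, regardless of the cue.
    """
    if rule == "VC":
        return chosen_side == cue_side
    if rule in ("TURN_L", "TURN_R"):
        return chosen_side == rule[-1]
    raise ValueError(f"unknown rule {rule!r}")


def _default_pd_positions() -> dict:
    # path coordinate (cm) along start runway -> central arm -> reward arm ->
    # return arm; see MazeConfig.path_length
    return {"VC_ON_PD": 70.0, "RWD_PD": 145.0, "RTN_PD": 255.0}


@dataclass(frozen=True)
class MazeConfig:
    """Geometry and acquisition constants of the automated T maze.

    The maze is a central arm (100 cm) with two 50 cm reward arms and return
    arms closing the loop back to a 35 x 40 cm start area.  Photodetector
    positions are expressed as coordinates along the canonical one-directional
    path (start area -> central arm -> chosen reward arm -> return arm).
    """

    central_arm_length: float = 100.0
    reward_arm_length: float = 50.0
    arm_width: float = 8.0
    start_area: tuple = (35.0, 40.0)
    #: path length traversed through the start area before the central arm
    start_runway: float = 20.0
    #: polyline length of a return arm (reward-arm end back to start runway)
    return_arm_length: float = 170.0
    pd_positions: dict = field(default_factory=_default_pd_positions)
    reward_volume_ul: float = 30.0
    video_dt: float = 1.0 / 30.0

    def __post_init__(self):
        for name in (
            "central_arm_length",
            "reward_arm_length",
            "arm_width",
            "start_runway",
            "return_arm_length",
            "video_dt",
        ):
            if getattr(self, name) <= 0:
                raise SessionValidationError(f"MazeConfig.{name} must be > 0")
        for kind, pos in self.pd_positions.items():
            if not 0 <= pos < self.path_length:
                raise SessionValidationError(
                    f"photodetector {kind} at {pos} cm is off the path "
                    f"(length {self.path_length} cm)"
                )

    @property
    def path_length(self) -> float:
        """Total path length of one trial lap (cm)."""
        return (
            self.start_runway
            + self.central_arm_length
            + self.reward_arm_length
            + self.return_arm_length
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_area"] = list(self.start_area)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MazeConfig":
        d = dict(d)
        d["start_area"] = tuple(d["start_area"])
        return cls(**d)


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one unit plus QC metadata."""

    unit_id: str
    times: np.ndarray
    waveform_ms: float | None = None
    opto_status: str = "untested"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise SessionValidationError("spike times must be 1-D")
        if self.times.size and self.times[0] < 0:
            raise SessionValidationError(
                f"unit {self.unit_id}: negative spike time"
            )
        if np.any(np.diff(self.times) <= 0):
            raise SessionValidationError(
                f"unit {self.unit_id}: spike times not strictly increasing"
            )

    def __eq__(self, other):
        return (
            isinstance(other, SpikeTrain)
            and self.unit_id == other.unit_id
            and np.array_equal(self.times, other.times)
            and self.waveform_ms == other.waveform_ms
            and self.opto_status == other.opto_status
        )


@dataclass
class TrackingSeries:
    """Head-LED position samples at the nominal video rate (~30 Hz).

    Missing frames are represented as time gaps, never interpolated here.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise SessionValidationError("tracking arrays must share a shape")
        if np.any(np.diff(self.times) <= 0):
            raise SessionValidationError(
                "tracking times not strictly increasing"
            )

    def __len__(self):
        return self.times.size

    def __eq__(self, other):
        return (
            isinstance(other, TrackingSeries)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )


@dataclass(frozen=True)
class TaskEvent:
    """A timestamped, typed maze event."""

    time: float
    kind: str
    side: str = "NA"
    payload: str = ""

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise SessionValidationError(f"unknown event kind {self.kind!r}")
        if self.side not in SIDES:
            raise SessionValidationError(f"unknown side {self.side!r}")
        if self.kind not in ARM_EVENT_KINDS and self.side != "NA":
            raise SessionValidationError(
                f"{self.kind} events carry no side (got {self.side!r})"
            )


@dataclass(frozen=True)
class Trial:
    """One lap of the maze: VC onset -> reward-arm PD -> return-arm PD."""

    index: int
    vc_on_time: float
    cue_side: str
    chosen_side: str
    rwd_pd_time: float
    rtn_pd_time: float
    rewarded: bool
    rule_in_force: str


@dataclass(frozen=True)
class Block:
    """Contiguous run of trials under one rule/strategy label (inclusive)."""

    start_trial: int
    end_trial: int
    label: str


@dataclass
class Session:
    """One recorded or synthetic session."""

    maze: MazeConfig
    spikes: list
    tracking: TrackingSeries | None
    events: list
    trials: list
    blocks: list
    meta: dict = field(default_factory=dict)
    initial_rule: str = "VC"

    def unit(self, unit_id: str | None = None) -> SpikeTrain:
        """Return the spike train with ``unit_id`` (default: first unit)."""
        if unit_id is None:
            if not self.spikes:
                raise SessionValidationError("session has no units")
            return self.spikes[0]
        for tr in self.spikes:
            if tr.unit_id == unit_id:
                return tr
        raise SessionValidationError(f"no unit {unit_id!r} in session")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def event_times(self, kind: str, side: str | None = None) -> np.ndarray:
        ts = [
            e.time
            for e in self.events
            if e.kind == kind and (side is None or e.side == side)
        ]
        return np.asarray(ts, dtype=float)

    def validate(self) -> None:
        """Check the cross-component invariants; raise on violation."""
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise SessionValidationError("events are not time ordered")
        keyed = {(e.kind, round(e.time, 9)) for e in self.events}
        for t in self.trials:
            if not (t.vc_on_time < t.rwd_pd_time < t.rtn_pd_time):
                raise SessionValidationError(
                    f"trial {t.index}: event times out of order "
                    f"(vc={t.vc_on_time}, rwd={t.rwd_pd_time}, "
                    f"rtn={t.rtn_pd_time})"
                )
            for kind, tt in (
                ("VC_ON_PD", t.vc_on_time),
                ("RWD_PD", t.rwd_pd_time),
                ("RTN_PD", t.rtn_pd_time),
            ):
                if (kind, round(tt, 9)) not in keyed:
                    raise SessionValidationError(
                        f"trial {t.index}: {kind} at {tt} s missing from "
                        "the event log"
                    )
            if t.rewarded != rule_is_rewarded(
                t.rule_in_force, t.cue_side, t.chosen_side
            ):
                raise SessionValidationError(
                    f"trial {t.index}: rewarded={t.rewarded} inconsistent "
                    f"with rule {t.rule_in_force}, cue {t.cue_side}, "
                    f"choice {t.chosen_side}"
                )
        if self.trials:
            if not self.blocks:
                raise SessionValidationError("non-empty session needs blocks")
            cursor = 0
            for b in self.blocks:
                if b.start_trial != cursor:
                    raise SessionValidationError(
                        f"block {b} does not start at trial {cursor}"
                    )
                if b.end_trial < b.start_trial:
                    raise SessionValidationError(f"empty block {b}")
                cursor = b.end_trial + 1
            if cursor != len(self.trials):
                raise SessionValidationError(
                    "blocks do not cover all trials "
                    f"({cursor} vs {len(self.trials)})"
                )

    def __eq__(self, other):
        return (
            isinstance(other, Session)
            and self.maze == other.maze
            and self.spikes == other.spikes
            and self.tracking == other.tracking
            and self.events == other.events
            and self.trials == other.trials
            and self.blocks == other.blocks
            and self.meta == other.meta
            and self.initial_rule == other.initial_rule
        )


# ---------------------------------------------------------------------------
# trial construction

def build_trials(events: list, initial_rule: str = "VC") -> list:
    """Assemble :class:`Trial` records from a time-ordered event log.

    One trial per ``VC_ON_PD`` event that is followed by a ``RWD_PD`` and
    then a ``RTN_PD`` before the next ``VC_ON_PD``.  A trial is rewarded iff
    a ``REWARD`` event falls between its reward-arm and return-arm PD
    crossings.  The rule in force is the payload of the most recent
    ``RULE_CHANGE`` at VC onset (``initial_rule`` before any change).

    Malformed triples (backtracking: a second ``VC_ON_PD`` before the
    ``RWD_PD``; or missing crossings) are excluded with a logged warning:
    the shaping protocol forbids backtracking, so they are protocol
    violations, not data.
    """
    events = sorted(events, key=lambda e: e.time)
    trials: list = []
    rule = initial_rule
    # indices of VC_ON_PD events
    vc_idx = [i for i, e in enumerate(events) if e.kind == "VC_ON_PD"]
    rule_changes = [(e.time, e.payload) for e in events if e.kind == "RULE_CHANGE"]

    def rule_at(t: float) -> str:
        r = initial_rule
        for tc, payload in rule_changes:
            if tc <= t:
                r = payload
            else:
                break
        return r

    for j, i0 in enumerate(vc_idx):
        i1 = vc_idx[j + 1] if j + 1 < len(vc_idx) else len(events)
        segment = events[i0 + 1 : i1]
        vc = events[i0]
        rwd = next((e for e in segment if e.kind == "RWD_PD"), None)
        if rwd is None:
            log.warning(
                "trial starting at VC onset %.3f s: no RWD_PD before the "
                "next VC onset; excluded", vc.time
            )
            continue
        rtn = next(
            (e for e in segment if e.kind == "RTN_PD" and e.time > rwd.time),
            None,
        )
        if rtn is None:
            log.warning(
                "trial starting at VC onset %.3f s: no RTN_PD after RWD_PD; "
                "excluded", vc.time
            )
            continue
        rewarded = any(
            e.kind == "REWARD" and rwd.time <= e.time <= rtn.time
            for e in segment
        )
        trials.append(
            Trial(
                index=len(trials),
                vc_on_time=vc.time,
                cue_side=vc.side,
                chosen_side=rwd.side,
                rwd_pd_time=rwd.time,
                rtn_pd_time=rtn.time,
                rewarded=rewarded,
                rule_in_force=rule_at(vc.time),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# unit quality control

def filter_units_by_duration(spikes: list, min_ms: float = 0.6) -> list:
    """Retain units whose spike waveform duration is >= ``min_ms``.

    Sub-threshold waveforms are not locus coeruleus spikes and are rejected.
    Units without a recorded duration are retained and flagged with a
    warning rather than silently dropped.
    """
    kept = []
    for tr in spikes:
        if tr.waveform_ms is None:
            log.warning(
                "unit %s has no waveform duration; retained unchecked",
                tr.unit_id,
            )
            kept.append(tr)
        elif tr.waveform_ms >= min_ms:
            kept.append(tr)
    return kept


@dataclass(frozen=True)
class OptoClassification:
    """Outcome of the opto-tagging entrainment test for one unit."""

    status: str  # "entrained" | "not_entrained" | "unclassifiable"
    pulse_rate_hz: float
    baseline_rate_hz: float

    @property
    def is_entrained(self) -> bool | None:
        if self.status == "unclassifiable":
            return None
        return self.status == "entrained"


def classify_opto_unit(
    train: SpikeTrain,
    pulse_times,
    pulse_dur_s: float = 0.1,
    baseline_window: tuple = (0.0, 0.0),
) -> OptoClassification:
    """Opto-tag a unit: entrained iff its rate within laser pulses, averaged
    over all pulses, is at least twice the baseline rate (boundary
    inclusive).

    ``pulse_times`` may be an array of pulse-onset times or a list of
    ``LASER_PULSE`` :class:`TaskEvent`.  ``baseline_window`` must be disjoint
    from every pulse.  A zero baseline rate makes the ratio undefined and the
    unit "unclassifiable".
    """
    if pulse_times and isinstance(pulse_times[0], TaskEvent):
        pulse_times = [e.time for e in pulse_times]
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size < 10:
        raise ValueError("need at least 10 laser pulses to classify a unit")
    b0, b1 = baseline_window
    if b1 <= b0:
        raise ValueError("baseline window must have positive length")
    if np.any((pulse_times < b1) & (pulse_times + pulse_dur_s > b0)):
        raise ValueError("baseline window overlaps laser stimulation")
    t = train.times
    in_pulse = 0
    for p in pulse_times:
        lo, hi = np.searchsorted(t, [p, p + pulse_dur_s])
        in_pulse += hi - lo
    pulse_rate = in_pulse / (pulse_times.size * pulse_dur_s)
    lo, hi = np.searchsorted(t, [b0, b1])
    baseline_rate = (hi - lo) / (b1 - b0)
    if baseline_rate == 0:
        log.warning(
            "unit %s: zero baseline rate, opto classification undefined",
            train.unit_id,
        )
        return OptoClassification("unclassifiable", pulse_rate, baseline_rate)
    status = "entrained" if pulse_rate >= 2.0 * baseline_rate else "not_entrained"
    return OptoClassification(status, pulse_rate, baseline_rate)


# ---------------------------------------------------------------------------
# on-disk bundle

_BUNDLE_FILES = (
    "meta.json",
    "events.csv",
    "spikes.csv",
    "units.json",
    "blocks.csv",
)


def write_session(session: Session, path) -> None:
    """Write a session as a plain-text directory bundle.

    Layout: ``meta.json`` (maze config, initial rule, provenance),
    ``events.csv`` (time_s, kind, side, payload), ``spikes.csv``
    (unit_id, time_s), ``units.json`` (unit metadata), ``tracking.csv``
    (time_s, x_cm, y_cm) and ``blocks.csv`` (start_trial, end_trial, label).
    Floats are written at full precision; writing is deterministic.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "maze": session.maze.to_dict(),
        "initial_rule": session.initial_rule,
        "meta": session.meta,
    }
    (path / "meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n"
    )
    pd.DataFrame(
        {
            "time_s": [e.time for e in session.events],
            "kind": [e.kind for e in session.events],
            "side": [e.side for e in session.events],
            "payload": [e.payload for e in session.events],
        }
    ).to_csv(path / "events.csv", index=False)
    unit_ids = np.concatenate(
        [np.repeat(tr.unit_id, tr.times.size) for tr in session.spikes]
    ) if session.spikes else np.array([], dtype=str)
    times = np.concatenate(
        [tr.times for tr in session.spikes]
    ) if session.spikes else np.array([])
    pd.DataFrame({"unit_id": unit_ids, "time_s": times}).to_csv(
        path / "spikes.csv", index=False
    )
    units = [
        {
            "unit_id": tr.unit_id,
            "waveform_ms": tr.waveform_ms,
            "opto_status": tr.opto_status,
        }
        for tr in session.spikes
    ]
    (path / "units.json").write_text(
        json.dumps(units, indent=1, sort_keys=True) + "\n"
    )
    if session.tracking is not None:
        pd.DataFrame(
            {
                "time_s": session.tracking.times,
                "x_cm": session.tracking.x,
                "y_cm": session.tracking.y,
            }
        ).to_csv(path / "tracking.csv", index=False)
    pd.DataFrame(
        {
            "start_trial": [b.start_trial for b in session.blocks],
            "end_trial": [b.end_trial for b in session.blocks],
            "label": [b.label for b in session.blocks],
        }
    ).to_csv(path / "blocks.csv", index=False)


def read_session(path) -> Session:
    """Read and fully validate a session bundle written by
    :func:`write_session`.

    Trials are rebuilt from the event log.  A missing ``tracking.csv`` is
    tolerated (kinematic analyses are then unavailable); any other missing
    file raises :class:`SessionLoadError`.
    """
    path = Path(path)
    for fname in _BUNDLE_FILES:
        if not (path / fname).exists():
            raise SessionLoadError(f"session bundle {path} is missing {fname}")
    meta = json.loads((path / "meta.json").read_text())
    maze = MazeConfig.from_dict(meta["maze"])
    ev = pd.read_csv(
        path / "events.csv",
        dtype={"kind": str, "side": str, "payload": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    events = [
        TaskEvent(float(r.time_s), r.kind, r.side, r.payload)
        for r in ev.itertuples()
    ]
    units_meta = json.loads((path / "units.json").read_text())
    sp = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str},
                     float_precision="round_trip")
    spikes = []
    for um in units_meta:
        t = sp.loc[sp.unit_id == um["unit_id"], "time_s"].to_numpy()
        spikes.append(
            SpikeTrain(
                um["unit_id"],
                t,
                um.get("waveform_ms"),
                um.get("opto_status", "untested"),
            )
        )
    tracking = None
    if (path / "tracking.csv").exists():
        tk = pd.read_csv(path / "tracking.csv",
                         float_precision="round_trip")
        tracking = TrackingSeries(
            tk.time_s.to_numpy(), tk.x_cm.to_numpy(), tk.y_cm.to_numpy()
        )
    else:
        log.warning(
            "bundle %s has no tracking.csv; kinematic analyses unavailable",
            path,
        )
    bl = pd.read_csv(path / "blocks.csv", dtype={"label": str})
    blocks = [
        Block(int(r.start_trial), int(r.end_trial), r.label)
        for r in bl.itertuples()
    ]
    initial_rule = meta.get("initial_rule", "VC")
    trials = build_trials(events, initial_rule)
    session = Session(
        maze=maze,
        spikes=spikes,
        tracking=tracking,
        events=events,
        trials=trials,
        blocks=blocks,
        meta=meta.get("meta", {}),
        initial_rule=initial_rule,
    )
    session.validate()
    return session
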