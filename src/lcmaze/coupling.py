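"""Firing-rate / acceleration coupling analyses.

The locus coeruleus fires just before self-initiated accelerations, so the
interesting quantities are (a) regressions of binned firing rate on binned
*positive* acceleration, inside and outside task-event windows, (b) a
+-1 s lag scan in 20 ms steps that finds the time shift of the acceleration
series maximising the rate-acceleration correlation (positive shift =
firing precedes acceleration), and (c) onset-based timing: percentile
-threshold onsets of the instantaneous firing rate (95th) and of
acceleration (97.5th), combined in a +-500 ms onset cross-correlogram whose
mean lag summarises how long firing leads movement.

Bin conventions follow the event analyses: 200 ms bins spanning [-1, 1) s
around each event, bins with firing rate below 0.1 Hz removed, and rate and
acceleration z-scored per unit-session before pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinematics import (
    KinematicSeries,
    compute_kinematics,
    gaussian_smooth,
    zscore,
)
from .session import Session

log = logging.getLogger(__name__)

MIN_RATE_HZ = 0.1

_ANCHOR_ATTR = {
    "VC_ON_PD": "vc_on_time",
    "RWD_PD": "rwd_pd_time",
    "RTN_PD": "rtn_pd_time",
}


def session_kinematics(session: Session,
                       smooth_sd_s: float = 0.066) -> KinematicSeries:
    """Kinematics of a session's tracking (convenience wrapper)."""
    if session.tracking is None:
        raise ValueError("session has no tracking; kinematics unavailable")
    return compute_kinematics(session.tracking, smooth_sd_s=smooth_sd_s)


def _anchor_times(session: Session, kind: str) -> np.ndarray:
    attr = _ANCHOR_ATTR[kind]
    return np.array([getattr(tr, attr) for tr in session.trials])


@dataclass
class PairedBins:
    """One-to-one (firing rate, acceleration) pairs on a common bin grid.

    ``rate``/``accel`` are the raw per-bin means; ``rate_z``/``accel_z``
    the per-unit-session z-scores over the surviving bins.
    """

    anchor_kind: str  # event kind or "OUTSIDE"
    times: np.ndarray  # absolute bin start times (s)
    rate: np.ndarray
    accel: np.ndarray
    rate_z: np.ndarray
    accel_z: np.ndarray
    n_anchors: int

    @property
    def n(self) -> int:
        return self.times.size


def _paired_bins(spike_times, kin, bin_starts, width, min_rate_hz):
    """Rates and mean accelerations for given absolute bin starts; drops
    low-rate bins and bins without valid acceleration samples."""
    bin_starts = np.asarray(bin_starts, dtype=float)
    lo = np.searchsorted(spike_times, bin_starts)
    hi = np.searchsorted(spike_times, bin_starts + width)
    rate = (hi - lo) / width
    at = kin.times[kin.valid]
    av = kin.accel[kin.valid]
    alo = np.searchsorted(at, bin_starts)
    ahi = np.searchsorted(at, bin_starts + width)
    cum = np.concatenate([[0.0], np.cumsum(av)])
    nacc = ahi - alo
    with np.errstate(invalid="ignore"):
        accel = np.where(
            nacc > 0, (cum[ahi] - cum[alo]) / np.maximum(nacc, 1), np.nan
        )
    keep = (rate >= min_rate_hz) & np.isfinite(accel)
    return bin_starts[keep], rate[keep], accel[keep]


def collect_event_bins(
    session: Session,
    unit_id: str | None = None,
    kind: str = "VC_ON_PD",
    window: tuple = (-1.0, 1.0),
    bin_width: float = 0.2,
    min_rate_hz: float = MIN_RATE_HZ,
    kin: KinematicSeries | None = None,
) -> PairedBins:
    """Paired rate/acceleration bins around every anchor of one event kind
    (200 ms bins spanning [-1, 1) s by default)."""
    anchors = _anchor_times(session, kind)
    if anchors.size == 0:
        raise ValueError(f"no {kind} anchors in session")
    if kin is None:
        kin = session_kinematics(session)
    a, b = window
    n_bins = int(round((b - a) / bin_width))
    starts = (anchors[:, None] + a + bin_width * np.arange(n_bins)).ravel()
    t = session.unit(unit_id).times
    times, rate, accel = _paired_bins(t, kin, starts, bin_width, min_rate_hz)
    if times.size >= 2 and rate.std(ddof=1) > 0 and accel.std(ddof=1) > 0:
        rz, az = zscore(rate), zscore(accel)
    else:
        rz = np.full(times.size, np.nan)
        az = np.full(times.size, np.nan)
    return PairedBins(kind, times, rate, accel, rz, az, anchors.size)


def exclusion_windows(session: Session,
                      half_widths=(("VC_ON_PD", 1.0), ("RTN_PD", 1.0),
                                   ("RWD_PD", 0.5))) -> list:
    """Merged +-half-width windows around the three task events."""
    iv = []
    for kind, half in half_widths:
        for a in _anchor_times(session, kind):
            iv.append((a - half, a + half))
    iv.sort()
    merged = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def collect_outside_bins(
    session: Session,
    unit_id: str | None = None,
    match_n: int | None = None,
    rng=None,
    bin_width: float = 0.1,
    min_rate_hz: float = MIN_RATE_HZ,
    kin: KinematicSeries | None = None,
) -> PairedBins:
    """Paired 100 ms bins over the session *excluding* +-1 s around the
    VC-onset and return-arm crossings and +-0.5 s around the reward-arm
    crossing, optionally down-sampled without replacement to ``match_n``
    bins (seeded) to match the event-window sample sizes."""
    if kin is None:
        kin = session_kinematics(session)
    t0 = float(kin.times[0])
    t1 = float(kin.times[-1])
    starts = np.arange(t0, t1 - bin_width, bin_width)
    merged = exclusion_windows(session)
    if merged:
        ms = np.array([s for s, _ in merged])
        me = np.array([e for _, e in merged])
        idx = np.searchsorted(ms, starts + bin_width, side="left") - 1
        inside = np.zeros(starts.size, dtype=bool)
        ok = idx >= 0
        inside[ok] = starts[ok] < me[idx[ok]]
        starts = starts[~inside]
    t = session.unit(unit_id).times
    times, rate, accel = _paired_bins(t, kin, starts, bin_width, min_rate_hz)
    if match_n is not None and times.size > match_n:
        if rng is None:
            raise ValueError("down-sampling requires an rng")
        pick = np.sort(rng.choice(times.size, size=match_n, replace=False))
        times, rate, accel = times[pick], rate[pick], accel[pick]
    elif match_n is not None and times.size < match_n:
        log.warning(
            "only %d outside-event bins survive (requested %d); using all",
            times.size, match_n,
        )
    if times.size >= 2 and rate.std(ddof=1) > 0 and accel.std(ddof=1) > 0:
        rz, az = zscore(rate), zscore(accel)
    else:
        rz = np.full(times.size, np.nan)
        az = np.full(times.size, np.nan)
    return PairedBins("OUTSIDE", times, rate, accel, rz, az, 0)


@dataclass
class CouplingRegression:
    scope: str
    slope: float
    r: float
    p: float
    n: int


def regress_rate_on_accel(bins: PairedBins,
                          positive_only: bool = True) -> CouplingRegression:
    """OLS of z-scored firing rate on z-scored acceleration, restricted to
    bins with positive (raw) acceleration: deceleration reflects a
    different behavioral state and is excluded."""
    mask = bins.accel > 0 if positive_only else np.ones(bins.n, dtype=bool)
    x = bins.accel_z[mask]
    y = bins.rate_z[mask]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("regression needs n >= 3 positive-acceleration bins")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate variance in regression input")
    lr = stats.linregress(x, y)
    return CouplingRegression(
        bins.anchor_kind, float(lr.slope), float(lr.rvalue),
        float(lr.pvalue), int(x.size),
    )


@dataclass
class LagScanResult:
    shifts_ms: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray
    best_shift_ms: float  # positive = firing precedes acceleration

    @property
    def best_r(self) -> float:
        i = int(np.flatnonzero(self.shifts_ms == self.best_shift_ms)[0])
        return float(self.r[i])


def lag_scan(
    session: Session,
    unit_id: str | None = None,
    kind: str = "VC_ON_PD",
    step_ms: float = 20.0,
    span_ms: float = 1000.0,
    window: tuple = (-1.0, 1.0),
    bin_width: float = 0.2,
    min_rate_hz: float = MIN_RATE_HZ,
    kin: KinematicSeries | None = None,
) -> LagScanResult:
    """Correlation between event-window firing-rate bins and the
    acceleration series displaced in ``step_ms`` steps over +-``span_ms``.

    At shift ``s`` each rate bin ``[t, t+w)`` is paired with the mean
    acceleration over ``[t+s, t+w+s)``, so the shift maximising r is the
    firing-to-acceleration lead.  Ties break toward the smallest absolute
    shift.
    """
    anchors = _anchor_times(session, kind)
    if anchors.size == 0:
        raise ValueError(f"no {kind} anchors in session")
    if kin is None:
        kin = session_kinematics(session)
    a, b = window
    n_bins = int(round((b - a) / bin_width))
    starts = (anchors[:, None] + a + bin_width * np.arange(n_bins)).ravel()
    t = session.unit(unit_id).times
    lo = np.searchsorted(t, starts)
    hi = np.searchsorted(t, starts + bin_width)
    rate = (hi - lo) / bin_width
    rate_keep = rate >= min_rate_hz
    at = kin.times[kin.valid]
    av = kin.accel[kin.valid]
    # cumulative integral for O(1) window means at arbitrary shifts
    seg = np.diff(at)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (av[:-1] + av[1:]) * seg)])

    def accel_mean(u0, u1):
        i0 = np.interp(u0, at, cum)
        i1 = np.interp(u1, at, cum)
        out = (i1 - i0) / (u1 - u0)
        out[(u0 < at[0]) | (u1 > at[-1])] = np.nan
        return out

    shifts = np.arange(-span_ms, span_ms + step_ms / 2, step_ms)
    r = np.full(shifts.size, np.nan)
    n_pairs = np.zeros(shifts.size, dtype=int)
    for i, s_ms in enumerate(shifts):
        s = s_ms / 1000.0
        acc = accel_mean(starts + s, starts + bin_width + s)
        keep = rate_keep & np.isfinite(acc)
        n_pairs[i] = int(keep.sum())
        if n_pairs[i] >= 3 and rate[keep].std() > 0 and acc[keep].std() > 0:
            r[i] = stats.pearsonr(rate[keep], acc[keep]).statistic
    if not np.any(np.isfinite(r)):
        raise ValueError("lag scan degenerate at every shift")
    rmax = np.nanmax(r)
    cand = np.flatnonzero(r == rmax)
    best = cand[np.argmin(np.abs(shifts[cand]))]
    return LagScanResult(shifts, r, n_pairs, float(shifts[best]))


@dataclass
class OnsetSet:
    """Upward threshold crossings of a rate or acceleration series.

    After a crossing the series must fall back below the threshold before a
    new onset can be registered (hysteresis at the same threshold), which
    prevents bin-jitter double counting.
    """

    kind: str  # "firing" | "accel"
    times: np.ndarray
    threshold: float
    percentile: float
    excluded: bool = False


def _upward_crossings(times: np.ndarray, values: np.ndarray,
                      threshold: float) -> np.ndarray:
    """Times of upward threshold crossings, linearly interpolated between
    the bracketing samples (removes the half-sample delay a sample-aligned
    onset would carry)."""
    if values.size == 0 or np.ptp(values) < 1e-8:
        return np.array([])  # flat series: nothing can cross
    above = values > threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if rising.size == 0:
        return np.array([])
    v0 = values[rising - 1]
    v1 = values[rising]
    frac = (threshold - v0) / (v1 - v0)
    return times[rising - 1] + frac * (times[rising] - times[rising - 1])


def detect_firing_onsets(
    spike_times,
    t_start: float,
    t_end: float,
    bin_s: float = 0.05,
    smooth_sd_s: float = 0.066,
    percentile: float = 95.0,
    exclude_at_or_below_hz: float = 4.0,
) -> OnsetSet:
    """Onsets of firing-rate increases.

    The instantaneous rate is the 50 ms-binned spike count converted to Hz
    and smoothed with the same Gaussian kernel as the kinematics; the
    threshold is the 95th percentile of that rate distribution over the
    session.  Sessions whose threshold is <= 4 Hz are flagged excluded
    (a single spike reaches 4 Hz in this estimate, so onsets would be
    noise).
    """
    edges = np.arange(t_start, t_end + bin_s, bin_s)
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), edges)
    rate = counts / bin_s
    rate = gaussian_smooth(rate, smooth_sd_s, dt=bin_s)
    centers = edges[:-1] + bin_s / 2
    thr = float(np.percentile(rate, percentile))
    onsets = _upward_crossings(centers, rate, thr)
    excluded = thr <= exclude_at_or_below_hz
    if excluded:
        log.info(
            "firing-onset threshold %.2f Hz <= %.1f Hz; session flagged "
            "excluded", thr, exclude_at_or_below_hz,
        )
    return OnsetSet("firing", onsets, thr, percentile, excluded)


def detect_accel_onsets(kin: KinematicSeries,
                        percentile: float = 97.5) -> OnsetSet:
    """Onsets of acceleration increases: upward crossings of the 97.5th
    percentile of the (valid) acceleration distribution."""
    ok = kin.valid & np.isfinite(kin.accel)
    if not np.any(ok):
        raise ValueError("no valid acceleration samples")
    thr = float(np.percentile(kin.accel[ok], percentile))
    onsets = _upward_crossings(kin.times[ok], kin.accel[ok], thr)
    return OnsetSet("accel", onsets, thr, percentile)


@dataclass
class OnsetCrossCorr:
    """Histogram of acceleration-onset lags around firing onsets.

    ``mean_lag_ms`` > 0 means acceleration follows firing.
    """

    bin_centers_ms: np.ndarray
    counts: np.ndarray
    mean_lag_ms: float
    n_pairs: int
    n_firing_onsets: int

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def restrict_onsets_near_events(onsets: OnsetSet, event_times,
                                half_width_s: float = 1.0) -> OnsetSet:
    """Keep onsets within +-``half_width_s`` of any given event time."""
    ev = np.sort(np.asarray(event_times, dtype=float))
    if ev.size == 0 or onsets.times.size == 0:
        return OnsetSet(onsets.kind, np.array([]), onsets.threshold,
                        onsets.percentile, onsets.excluded)
    idx = np.clip(np.searchsorted(ev, onsets.times), 1, ev.size - 1)
    near = np.minimum(
        np.abs(onsets.times - ev[idx - 1]),
        np.abs(onsets.times - ev[np.minimum(idx, ev.size - 1)]),
    ) <= half_width_s
    return OnsetSet(onsets.kind, onsets.times[near], onsets.threshold,
                    onsets.percentile, onsets.excluded)


def onset_lag_crosscorr(
    firing_onsets: OnsetSet,
    accel_onsets: OnsetSet,
    window_ms: float = 500.0,
    bin_ms: float = 20.0,
) -> OnsetCrossCorr:
    """Cross-correlogram of acceleration onsets triggered on firing onsets.

    For every firing onset, all acceleration-onset lags within
    +-``window_ms`` enter the histogram and the mean lag (all pairs, not
    nearest-only).  An empty result is returned flagged, not raised.
    """
    f = firing_onsets.times
    a = np.asarray(accel_onsets.times, dtype=float)
    w = window_ms / 1000.0
    lags = []
    for ft in f:
        lo, hi = np.searchsorted(a, [ft - w, ft + w])
        if hi > lo:
            lags.append((a[lo:hi] - ft) * 1000.0)
    lags = np.concatenate(lags) if lags else np.array([])
    n_bins = int(round(2 * window_ms / bin_ms))
    edges = -window_ms + bin_ms * np.arange(n_bins + 1)
    counts, _ = np.histogram(lags, edges)
    centers = edges[:-1] + bin_ms / 2
    mean_lag = float(lags.mean()) if lags.size else np.nan
    if not lags.size:
        log.warning("no acceleration onsets within the window of any "
                    "firing onset")
    return OnsetCrossCorr(centers, counts, mean_lag, int(lags.size),
                          int(f.size))
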