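"""Speed and acceleration from LED tracking, plus binning/normalisation
primitives shared by all firing-kinematics analyses.

Instantaneous speed is the distance traversed by the head LED per video
frame divided by the frame interval (~33 ms).  Each speed estimate is
assigned to the *midpoint* of its frame interval; acceleration, the
difference of consecutive (smoothed) speeds divided by the interval, then
lands back on the original tracking timestamps.  This centered assignment
keeps the kinematic series aligned with the spike stream to well under one
video frame, which matters because the firing-to-acceleration lags of
interest are themselves only one or two frames long.

Tracking gaps larger than ``max_gap_factor`` video frames invalidate the
samples that straddle them; nothing is interpolated across a gap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class KinematicSeries:
    """A sampled kinematic signal; ``accel`` may be all-NaN before
    :func:`compute_acceleration` has run.  ``valid`` flags samples not
    contaminated by tracking gaps."""

    times: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        n = self.times.size
        if not (self.speed.size == self.accel.size == self.valid.size == n):
            raise ValueError("kinematic series arrays must share a length")


@dataclass
class BinnedSeries:
    """Per-bin means on a fixed half-open grid relative to an anchor."""

    bin_starts: np.ndarray
    width: float
    values: np.ndarray
    n_samples: np.ndarray


def compute_speed(tracking, max_gap_factor: float = 2.0,
                  video_dt: float | None = None) -> KinematicSeries:
    """Instantaneous speed from a :class:`~lcmaze.session.TrackingSeries`.

    ``speed[i] = |p[i+1] - p[i]| / (t[i+1] - t[i])`` assigned to the interval
    midpoint.  Samples across gaps longer than ``max_gap_factor`` nominal
    frames are marked invalid.
    """
    t = np.asarray(tracking.times, dtype=float)
    if t.size < 2:
        log.warning("fewer than 2 tracking samples; empty speed series")
        z = np.array([])
        return KinematicSeries(z, z.copy(), z.copy(), np.array([], dtype=bool))
    dt = np.diff(t)
    if video_dt is None:
        video_dt = float(np.median(dt))
    dx = np.diff(np.asarray(tracking.x, dtype=float))
    dy = np.diff(np.asarray(tracking.y, dtype=float))
    speed = np.hypot(dx, dy) / dt
    mid = t[:-1] + 0.5 * dt
    valid = dt <= max_gap_factor * video_dt
    return KinematicSeries(mid, speed, np.full(mid.size, np.nan), valid)


def gaussian_kernel(sd_samples: float) -> np.ndarray:
    """Discrete Gaussian kernel truncated at +-3 sd, normalised to sum 1."""
    radius = max(1, int(math.ceil(3.0 * sd_samples)))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd_samples) ** 2)
    return k / k.sum()


def gaussian_smooth(values, sd: float, dt: float = 1.0,
                    valid=None) -> np.ndarray:
    """Gaussian-smooth a uniformly sampled series.

    ``sd`` is in the units of ``dt`` (so pass seconds with ``dt`` the sample
    interval, or samples with ``dt=1``).  The kernel is truncated at +-3 sd
    and renormalised at edges and across invalid samples, so a constant
    series maps to itself.  If the sd is below one sample interval smoothing
    would be a near-delta; a warning is logged and the input returned.
    """
    values = np.asarray(values, dtype=float)
    if sd <= 0:
        raise ValueError("sd must be > 0")
    sd_samples = sd / dt
    if sd_samples < 1.0:
        log.warning(
            "smoothing sd (%.4g) below one sample interval; no-op", sd
        )
        return values.copy()
    if valid is None:
        valid = np.isfinite(values)
    m = np.asarray(valid, dtype=float)
    k = gaussian_kernel(sd_samples)
    num = np.convolve(np.where(m > 0, values, 0.0), k, mode="same")
    den = np.convolve(m, k, mode="same")
    out = np.full(values.shape, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def compute_acceleration(speed_series: KinematicSeries) -> KinematicSeries:
    """Acceleration as the difference of consecutive speed samples divided
    by their time interval, assigned to the midpoint of the two speed
    timestamps (i.e. back onto the original tracking grid)."""
    t = speed_series.times
    v = speed_series.speed
    if t.size < 2:
        log.warning("fewer than 2 speed samples; empty acceleration series")
        z = np.array([])
        return KinematicSeries(z, z.copy(), z.copy(), np.array([], dtype=bool))
    dt = np.diff(t)
    acc = np.diff(v) / dt
    mid = t[:-1] + 0.5 * dt
    vmid = 0.5 * (v[:-1] + v[1:])
    valid = (
        speed_series.valid[:-1]
        & speed_series.valid[1:]
        & np.isfinite(acc)
    )
    return KinematicSeries(mid, vmid, acc, valid)


def compute_kinematics(tracking, smooth_sd_s: float = 0.066,
                       max_gap_factor: float = 2.0,
                       smooth: bool = True) -> KinematicSeries:
    """Full pipeline: speed -> Gaussian smoothing (default sd two video
    frames) -> acceleration.  Returns a series on (the interior of) the
    tracking time grid with both speed and acceleration filled."""
    sp = compute_speed(tracking, max_gap_factor=max_gap_factor)
    if sp.times.size < 2:
        return sp
    if smooth:
        dt = float(np.median(np.diff(sp.times)))
        sm = gaussian_smooth(sp.speed, smooth_sd_s, dt=dt, valid=sp.valid)
        sp = KinematicSeries(sp.times, sm, sp.accel, sp.valid)
    return compute_acceleration(sp)


def bin_mean(times, values, anchor: float = 0.0,
             window: tuple = (-1.0, 1.0), width: float = 0.2,
             valid=None) -> BinnedSeries:
    """Per-bin means of samples on a half-open grid ``[a, b)`` relative to
    ``anchor``.  Empty bins get ``n_samples = 0`` and NaN value.  ``width``
    must divide the window length."""
    a, b = window
    n_bins = (b - a) / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide the window length")
    n_bins = int(round(n_bins))
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if valid is not None:
        times = times[np.asarray(valid, dtype=bool)]
        values = values[np.asarray(valid, dtype=bool)]
    rel = times - anchor
    inside = (rel >= a) & (rel < b)
    idx = np.floor((rel[inside] - a) / width).astype(int)
    # guard right-edge float round-up
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=values[inside], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    out = np.full(n_bins, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    starts = a + width * np.arange(n_bins)
    return BinnedSeries(starts, width, out, counts)


def zscore(values) -> np.ndarray:
    """Standardise to mean 0 and sample SD 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zscore undefined for zero-variance input")
    return (x - x.mean()) / sd
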