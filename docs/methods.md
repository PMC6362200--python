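# Methods

## The task and the data model

A session is one continuous recording of a rat running laps on an automated
T maze: a 20 cm start runway, a 100 cm central arm, two 50 cm reward arms
and return arms closing the loop (represented as a 1-D path coordinate of
340 cm per lap, mapped to 2-D for the tracking output). Three infrared
photodetectors (PDs) timestamp task events: the central-arm PD turns the
visual cue (VC) on and starts a trial, the reward-arm PD triggers reward
delivery, the return-arm PD turns the VC off. Under the VC rule the arm in
front of the lit screen is rewarded; under the Turn rule one fixed arm is.
The rule switches automatically when the animal reaches at least 18 correct
of the last 20 trials (moving window, counting only trials since the
previous switch so that two switches cannot fire back-to-back off the same
window).

Time is seconds from session start and every analysis window is half-open
`[a, b)`. Sessions are stored as plain-text bundles; trials are rebuilt
from the event log on load, so round-tripping is exact by construction.

## The synthetic generator

The generator's defaults are the study conditions; each piece is chosen to
carry exactly the statistical structure the analyses assume.

**Cue sequence.** Backtracking search with randomised branch order over the
three constraints: no side lit more than 2 consecutive trials; a strict
two-trial alternation spanning at most 4 trials (the most literal reading
of "the alternation did not repeat more than twice", isolated in one
predicate); at most 5 same-side cues in any 8 successive trials. All three
are suffix-local, so checking each extension guarantees whole-sequence
validity, and backtracking guarantees termination for any length.

**Agent.** Follows its *attended* rule with probability `p_follow_rule`
(default 0.9, near the 18/20 criterion), updates the attended rule
`attended_rule_lag` trials after a rule change (default 3), and otherwise
guesses with a side bias. Blocks are delimited at rule changes and at the
agent's strategy changes. The agent is an acknowledged invention — the
original behavior came from rats.

**Kinematics.** Per lap: a pause in the start area (1.5 s at ~1 cm/s), a
half-cosine ramp to a 30 cm/s cruise, a raised-cosine speed bump before
each PD crossing whose rising half is a positive acceleration pulse of peak
40 cm/s² lasting 0.8 s and beginning 0.8 s before the crossing (so the
acceleration occupies roughly the second before the crossing, and the
symmetric deceleration follows it), a 2.5 s dwell at the reward well, and
an Ornstein–Uhlenbeck speed fluctuation (sd 3 cm/s at cruise, correlation
time 0.3 s, scaled with the local base speed). The OU term matters: a
noiseless smooth bump has an autocorrelation ~0.8 s wide and cannot
localise a 35–100 ms lead at 20 ms resolution; the fast, acceleration-
coupled fluctuations are what give the lag estimators their timing
information, as trial-to-trial variability does in real data. Bump anchor
times are made self-consistent with the integrated trajectory by
fixed-point iteration, and positions are integrated trapezoidally so that
the tracking-derived acceleration coincides exactly with the acceleration
signal driving the spikes. Exact (sub-frame) PD crossing times become the
event timestamps; tracking is sampled at 30 Hz.

**Spikes.** Inhomogeneous Poisson by thinning against an envelope computed
from the configuration maxima:
`lambda(t) = b · g_ev(t) · s_rwd(t) + g_a · max(0, a(t + delta))` with
baseline `b = 2 Hz`; multiplicative event gains over the `[-1, 0) s`
before the VC-onset (1.5) and return-arm (1.4) crossings; suppression to
0.44 of baseline over `[1, 2) s` after the reward-arm crossing; additive
coupling `g_a = 0.05 Hz/(cm/s²)` to positive acceleration evaluated at
`t + delta` with `delta = 35 ms` (firing leads acceleration); and an
optional novelty gain over the 0.5 s *after* VC onset on trials following
the first rule shift. The event-gain window spans the full second before
the crossing rather than only `[-0.5, 0)`: the peak statistic is the max
of the two pre-event 0.5 s bins, so a gain confined to the late bin would
make the expected ratio `max(g, 1)` and suppressive gains unrecoverable;
with equal bin means the ratio is a direct probe of the gain. Acceleration
magnitudes are free parameters — the source data never quantify them — and
are flagged as such here.

An opto-tagging block (2 Hz pulse train, 100 ms pulses, within-pulse rate
= gain × baseline) can be appended for unit-identification tests; a unit
counts as noradrenergic if its within-pulse rate averaged over pulses is
at least twice baseline (boundary inclusive; a zero baseline makes the
unit "unclassifiable" rather than false). Spike waveforms below 0.6 ms
duration are rejected by the QC filter; units without a recorded duration
are retained and flagged.

All randomness descends from one root seed through spawned child streams
(cues, behavior, trajectory, per-unit spikes, laser), so a (config, seed)
pair fully determines every output byte.

## Numerical conventions

* **Speed/acceleration.** Speed is per-frame displacement over the frame
  interval (~33 ms), assigned to the interval *midpoint*; the speed series
  is Gaussian-smoothed (sd = 2 frames ≈ 66 ms, kernel truncated at ±3 sd
  and renormalised at edges and gaps); acceleration is the difference of
  consecutive smoothed speeds over their interval, which lands back on the
  original tracking timestamps. Centered assignment keeps the kinematic
  series aligned with the spike stream: backward labelling would delay
  acceleration by a full frame, the same order as the lags being estimated.
  Frames across tracking gaps longer than two nominal intervals are masked,
  never interpolated.
* **Binning.** Half-open bins; a spike exactly at an anchor falls in the
  bin starting at 0. Bins with firing rate below 0.1 Hz are removed (for
  the 100–200 ms widths used this removes exactly the empty bins); empty
  kinematic bins are excluded, not zero-filled. Rates and accelerations
  are z-scored (sample SD) per unit-session before pooling; regressions
  use positive raw acceleration only.
* **Lag scan.** Shifts −1000…+1000 ms in 20 ms steps; at shift `s` the
  rate bin `[t, t+w)` is paired with mean acceleration over
  `[t+s, t+w+s)` (cumulative-integral interpolation), so positive best
  shifts mean firing precedes acceleration. Ties break toward the smallest
  absolute shift.
* **Onsets.** Instantaneous rate = 50 ms-binned counts in Hz, smoothed
  with the same kernel as the kinematics; thresholds are the 95th (rate)
  and 97.5th (acceleration) percentiles over the session. Crossing times
  are linearly interpolated between the bracketing samples (a
  sample-aligned onset would be late by half a bin, ~25 ms for the rate
  series — material at the 35 ms scale). After a crossing the series must
  fall below the threshold before a new onset counts (hysteresis at the
  same threshold). Sessions whose rate threshold is ≤ 4 Hz are flagged
  excluded, since a single spike reaches 4 Hz in this estimate. The onset
  cross-correlogram averages *all* acceleration-onset lags within ±500 ms
  of each firing onset (nearest-only is available as an option).
* **Statistics.** One-sample t-tests of response ratios against 1 (an
  all-ones input returns t = 0, p = 1 rather than erroring; zero variance
  away from the null errors). The rule-shift comparison is the Wilcoxon
  rank sum via `scipy.stats.mannwhitneyu` (asymptotic with tie and
  continuity corrections — 0.5 s LC spike counts are small and heavily
  tied; empirical size ≈ 0.04 at nominal 0.05). Block comparisons use
  Welch t-tests with Holm–Bonferroni adjustment over the block pairs
  within each anchor kind. Population ratio–ratio association uses Pearson
  r with the least-squares slope.

## What the tests show — and their limits

Parameter-recovery tests drive the full pipeline on generated sessions:
event gains 0.5–3 are recovered by the VC-onset response ratio,
suppression 0.4 by the reward-site ratio, a 100 ms firing lead by the lag
scan to within one 20 ms step, and a 35 ms lead by the onset
cross-correlogram mean lag to within the ±15 ms band. Two estimator
properties discovered in this exercise are worth stating plainly:

* The peak statistic (max of two equal-mean noisy bins) is biased upward
  by ≈ σ/√π of the window-mean noise — about 2–3 standard errors at 200
  trials and 20 sessions — so recovery is asserted against an independent
  Poisson-count Monte-Carlo oracle of the statistic's expectation, not
  against the bare gain; the residual discrepancy bound (12 % of the gain)
  is stated alongside.
* The onset mean lag is pulled toward zero by noise-driven onset pairs and
  pushed upward by the 95th-vs-97.5th percentile threshold mismatch (the
  acceleration threshold sits at a higher signal level than the rate
  threshold, adding the rise time between those levels). At the recovery
  configuration these partially cancel; the measured grand mean is ~25 ms
  for a true 35 ms lead. The same biases act on real recordings analysed
  with these definitions.

Null calibrations (no shift in firing at the rule change; zero
acceleration coupling) hold the empirical type-I error of the rule-shift
test and the coupling regression inside [0.03, 0.07] at α = 0.05 over 200
replicates. Problem sizes in the test suite (200-trial sessions, 20 seeds
for recovery; 48/25-trial sessions for the 200-replicate null studies;
100-trial sessions for lag recovery) are the package's chosen study
scales.

What the generator does **not** emulate: bursty non-Poisson LC discharge
(spike doublets, post-burst suppression), pupil/autonomic covariates,
tracking dropouts and LED jitter (available but off by default), real
rats' heterogeneous strategies, and any biophysics. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not robustness to every property of real recordings.

## Known limitations

* The reported per-event lag-scan means in the source literature average an
  unstated per-session statistic over local maxima; this package reports
  per-session best shifts and leaves that ambiguity documented.
* With 20 ms steps, leads below ~40 ms are resolution-limited in the lag
  scan; the onset cross-correlogram is the finer instrument there.
* The Wilcoxon defaults to per-unit analysis; whether the original
  analysis pooled units within sessions is unknown, so both are exposed.
* `classify_opto_unit` assumes pulse windows and baseline are disjoint and
  refuses otherwise; entrainment at exactly twice baseline counts as
  entrained by definition.
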