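# lcmaze

Analysis of locus coeruleus (LC) unit activity during a self-paced T-maze
rule-shift task, together with a synthetic session generator that stands in
for the (unreleased) recordings.

## The scientific problem

Noradrenergic LC neurons fire tonically at 1–3 Hz but respond phasically to
salient events. In rats running a self-paced visual/spatial discrimination
task on an automated T maze, LC units increase firing *just before* the
photodetector crossings that the animal itself triggers, are suppressed at
the reward site, and their firing precedes locomotor acceleration by a few
tens of milliseconds. The quantities of interest are:

* **Response ratios** — peak windowed firing rate divided by the baseline
  rate in the `[-1.5, -1) s` window before visual-cue (VC) onset. The peak
  is the greater of the mean rates in the `[-1, -0.5)` and `[-0.5, 0) s`
  bins before the VC-onset (or return-arm) crossing, the mean rate in
  `[-0.5, 0) s` before the reward-arm crossing, or the mean rate in
  `[1, 2) s` after it (reward site). A ratio of 1 means no change.
* **Rule-shift comparison** — Wilcoxon rank-sum on spike counts in the
  0.5 s after VC onset, before vs after the first change of the reward
  contingency (the 18-correct-of-last-20 moving-window criterion drives the
  switches), plus Welch t-tests between trial blocks with Holm–Bonferroni
  correction.
* **Firing–acceleration coupling** — OLS of z-scored firing rate on
  z-scored *positive* acceleration in 200 ms bins around task events (and
  in 100 ms bins outside them, down-sampled to matched n); a ±1 s lag scan
  in 20 ms steps of the rate–acceleration correlation; and onset timing:
  95th-percentile threshold crossings of the instantaneous firing rate
  vs 97.5th-percentile crossings of acceleration, combined in a ±500 ms
  onset cross-correlogram whose mean lag measures how long firing leads
  movement.

Because the original recordings are not public, the package ships a
first-class generator (`lcmaze.synthetic`) producing complete sessions:
constrained pseudorandom cue sequences, a behaving agent with criterion-
driven rule switches, 30 Hz maze-path kinematics with pre-photodetector
acceleration bumps, and LC-like spikes from an inhomogeneous Poisson
process

```
lambda(t) = b * event_gain(t) * reward_suppression(t)
            + g_a * max(0, a(t + delta))
```

sampled exactly by thinning, where `delta` is the configurable firing lead
over acceleration. Every analysis can therefore be validated by parameter
recovery against known ground truth.

## Worked example

```python
import lcmaze as lm

cfg = lm.SimConfig(n_trials=80, seed=1)     # study-condition defaults
s = lm.simulate_session(cfg)
for kind in ("VC_ONSET", "VC_OFF", "RWD_PD", "REWARD_SITE"):
    rr = lm.response_ratio(s, kind)
    print(f"{kind:12s} peak {rr.peak_rate_hz:5.2f} Hz  "
          f"baseline {rr.baseline_rate_hz:4.2f} Hz  ratio {rr.ratio:4.2f}")
kin = lm.session_kinematics(s)
ls = lm.lag_scan(s, kind="VC_ON_PD", kin=kin)
print(f"lag scan best shift: {ls.best_shift_ms:+.0f} ms (r = {ls.best_r:.2f})")
```

prints

```
VC_ONSET     peak  4.25 Hz  baseline 2.52 Hz  ratio 1.68
VC_OFF       peak  4.58 Hz  baseline 2.52 Hz  ratio 1.81
RWD_PD       peak  3.55 Hz  baseline 2.52 Hz  ratio 1.41
REWARD_SITE  peak  0.96 Hz  baseline 2.52 Hz  ratio 0.38
lag scan best shift: +60 ms (r = 0.24)
```

The pre-event ratios exceed 1 (firing builds up before the crossings the
rat is about to trigger — here a combination of the configured event gains
and the acceleration coupling), the reward-site ratio is far below 1
(suppression while the rat consumes the reward), and the lag scan finds the
correlation maximised with firing leading acceleration.

The same pipeline is available from the shell:

```bash
lcmaze simulate --config sim.yaml --out session/
lcmaze analyze --bundle session/ --out results/ --seed 0
lcmaze report --results results/
```

`analyze` writes tidy CSVs (`ratios.csv`, `tests.csv`, `regressions.csv`,
`lagscan.csv`, `onsets.csv`, `crosscorr.csv`); `report` renders them as a
markdown summary (optionally with figures via `--plots`). Session bundles
are plain-text directories (`events.csv`, `spikes.csv`, `tracking.csv`,
`units.json`, `blocks.csv`, `meta.json`) documented in
`lcmaze.session.write_session`.

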