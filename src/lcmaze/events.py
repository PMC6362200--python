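"""Peri-event analyses of locus coeruleus unit activity.

Implements the peri-event time histogram (PETH), the four windowed
response-ratio statistics with their population tests, the first-rule-shift
Wilcoxon comparison, and block-wise firing comparisons with Holm-Bonferroni
correction.

All four response ratios share one baseline: the mean firing rate in the
``[-1.5, -1)`` s window preceding VC onset (the baseline is *not*
re-anchored for the reward-site ratio).  The numerator depends on the event:

* ``VC_ONSET``: the greater of the mean rates in the two 0.5 s bins
  ``[-1, -0.5)`` and ``[-0.5, 0)`` before the central-arm (VC-onset)
  photodetector crossing;
* ``VC_OFF``: the same construction before the return-arm crossing;
* ``RWD_PD``: the mean rate in ``[-0.5, 0)`` before the reward-arm
  crossing (a briefer window, to avoid contamination by VC-onset activity);
* ``REWARD_SITE``: the mean rate in ``[1, 2)`` s after the reward-arm
  crossing, when the rat is at the reward well.

Ratios are (mean peak rate over trials) / (mean baseline rate over trials),
not means of per-trial ratios, which are unstable at tonic LC rates below
3 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .session import Session

log = logging.getLogger(__name__)

RATIO_KINDS = ("VC_ONSET", "VC_OFF", "RWD_PD", "REWARD_SITE")

#: shared baseline window, relative to VC onset
BASELINE_WINDOW = (-1.5, -1.0)


def _counts_in_windows(spike_times: np.ndarray, starts, width: float):
    """Spike count per half-open window [s, s+width)."""
    starts = np.asarray(starts, dtype=float)
    lo = np.searchsorted(spike_times, starts)
    hi = np.searchsorted(spike_times, starts + width)
    return hi - lo


@dataclass
class Peth:
    """Per-trial spike counts on a fixed bin grid around an alignment
    event, plus trial-averaged rates (Hz)."""

    alignment: str
    window: tuple
    bin_width: float
    counts: np.ndarray  # (n_trials, n_bins) int
    n_trials: int

    @property
    def bin_starts(self) -> np.ndarray:
        a, b = self.window
        return a + self.bin_width * np.arange(self.counts.shape[1])

    @property
    def rates(self) -> np.ndarray:
        return self.counts.mean(axis=0) / self.bin_width


def build_peth(spike_times, anchors, window=(-2.0, 2.0),
               bin_width: float = 0.1, alignment: str = "") -> Peth:
    """Bin spikes relative to each anchor on a half-open grid.

    A spike exactly at an anchor falls in the bin starting at 0.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size == 0:
        raise ValueError("build_peth needs at least one anchor event")
    a, b = window
    n_bins = (b - a) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide the window length")
    n_bins = int(round(n_bins))
    spike_times = np.asarray(spike_times, dtype=float)
    counts = np.zeros((anchors.size, n_bins), dtype=int)
    for i, anchor in enumerate(anchors):
        rel = spike_times - anchor
        rel = rel[(rel >= a) & (rel < b)]
        idx = np.minimum(((rel - a) / bin_width).astype(int), n_bins - 1)
        np.add.at(counts[i], idx, 1)
    return Peth(alignment, (a, b), bin_width, counts, anchors.size)


@dataclass
class ResponseRatioResult:
    kind: str
    peak_rate_hz: float
    baseline_rate_hz: float
    ratio: float
    windows: dict


def response_ratio(session: Session, kind: str,
                   unit_id: str | None = None) -> ResponseRatioResult:
    """Windowed peak/baseline response ratio for one unit (see module
    docstring for the window definitions).  Raises if the session has no
    trials or a zero baseline rate (ratio undefined)."""
    if kind not in RATIO_KINDS:
        raise ValueError(f"unknown response-ratio kind {kind!r}")
    if not session.trials:
        raise ValueError("session has no trials")
    t = session.unit(unit_id).times
    vc = np.array([tr.vc_on_time for tr in session.trials])
    rwd = np.array([tr.rwd_pd_time for tr in session.trials])
    rtn = np.array([tr.rtn_pd_time for tr in session.trials])
    b0, b1 = BASELINE_WINDOW
    baseline = _counts_in_windows(t, vc + b0, b1 - b0).mean() / (b1 - b0)
    windows = {"baseline": (b0, b1)}
    if kind in ("VC_ONSET", "VC_OFF"):
        anchors = vc if kind == "VC_ONSET" else rtn
        early = _counts_in_windows(t, anchors - 1.0, 0.5).mean() / 0.5
        late = _counts_in_windows(t, anchors - 0.5, 0.5).mean() / 0.5
        peak = max(early, late)
        windows["peak"] = ((-1.0, -0.5), (-0.5, 0.0))
    elif kind == "RWD_PD":
        peak = _counts_in_windows(t, rwd - 0.5, 0.5).mean() / 0.5
        windows["peak"] = (-0.5, 0.0)
    else:  # REWARD_SITE
        peak = _counts_in_windows(t, rwd + 1.0, 1.0).mean() / 1.0
        windows["peak"] = (1.0, 2.0)
    if baseline == 0:
        raise ValueError(
            "zero baseline rate in [-1.5, -1) s before VC onset; "
            "response ratio undefined"
        )
    return ResponseRatioResult(kind, float(peak), float(baseline),
                               float(peak / baseline), windows)


@dataclass
class PopulationTestResult:
    mean: float
    sem: float
    t: float
    df: int
    p: float


def ratio_population_test(ratios) -> PopulationTestResult:
    """One-sample two-sided t-test of per-session response ratios against
    the null value 1 (no change from baseline)."""
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValueError("population test needs at least 2 sessions")
    if x.std(ddof=1) == 0:
        if x[0] == 1.0:  # exactly the null everywhere: no evidence either way
            return PopulationTestResult(1.0, 0.0, 0.0, int(x.size - 1), 1.0)
        raise ValueError("degenerate test: zero variance across sessions")
    res = stats.ttest_1samp(x, popmean=1.0)
    return PopulationTestResult(
        float(x.mean()), float(stats.sem(x)), float(res.statistic),
        int(x.size - 1), float(res.pvalue),
    )


@dataclass
class RatioRegressionResult:
    r: float
    df: int
    p: float
    slope: float
    intercept: float


def ratio_ratio_regression(x, y) -> RatioRegressionResult:
    """Pearson correlation and least-squares line between two sets of
    per-session response ratios (e.g. VC-OFF vs VC-onset)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    lr = stats.linregress(x, y)
    return RatioRegressionResult(
        float(lr.rvalue), int(x.size - 1), float(lr.pvalue),
        float(lr.slope), float(lr.intercept),
    )


@dataclass
class RuleShiftResult:
    statistic: float
    p: float
    pre_counts: np.ndarray
    post_counts: np.ndarray
    split_trial: int
    status: str  # "ok" | "degenerate"


def rule_shift_test(session: Session, unit_id: str | None = None,
                    window_s: float = 0.5) -> RuleShiftResult:
    """Wilcoxon rank-sum comparison of spike counts in the ``[0, 0.5)`` s
    window after VC onset, before vs after the first rule shift.

    The split is at the first trial whose rule differs from the session's
    starting rule.  If all counts are zero the test is degenerate and
    flagged rather than computed.
    """
    trials = session.trials
    if not trials:
        raise ValueError("session has no trials")
    first_rule = trials[0].rule_in_force
    split = next(
        (i for i, tr in enumerate(trials) if tr.rule_in_force != first_rule),
        None,
    )
    if split is None:
        raise ValueError("session contains no rule change")
    if split < 5 or len(trials) - split < 5:
        raise ValueError(
            f"need >= 5 trials on each side of the shift (got {split} / "
            f"{len(trials) - split})"
        )
    t = session.unit(unit_id).times
    vc = np.array([tr.vc_on_time for tr in trials])
    counts = _counts_in_windows(t, vc, window_s)
    pre, post = counts[:split], counts[split:]
    if counts.max() == 0:
        log.warning("all VC-window spike counts are zero; degenerate test")
        return RuleShiftResult(np.nan, np.nan, pre, post, split, "degenerate")
    res = stats.mannwhitneyu(pre, post, alternative="two-sided")
    return RuleShiftResult(
        float(res.statistic), float(res.pvalue), pre, post, split, "ok"
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


@dataclass
class BlockComparisonResult:
    anchor_kind: str
    block_indices: list  # indices into session.blocks that were compared
    block_means: np.ndarray  # per-block mean window rate (Hz)
    pairs: list  # (i, j) pairs of positions in block_indices
    p_raw: np.ndarray
    p_adj: np.ndarray
    earliest_block_higher: np.ndarray  # vs each later block


#: pre-event window lengths (s) per anchor kind
BLOCK_WINDOWS = {"VC_ON_PD": 1.0, "RTN_PD": 1.0, "RWD_PD": 0.5}


def block_rate_comparison(
    session: Session,
    unit_id: str | None = None,
    windows: dict | None = None,
) -> dict:
    """Pairwise Welch t-tests of per-trial pre-event firing rates between
    trial blocks, Holm-Bonferroni corrected within each anchor kind.

    Windows are the 1 s before the VC-onset and return-arm crossings and
    the 0.5 s before the reward-arm crossing.  Blocks with fewer than two
    trials are dropped with a warning; at least two usable blocks are
    required.  Also reports whether the earliest block's mean exceeds each
    later block's (task engagement fading over the session).
    """
    if windows is None:
        windows = BLOCK_WINDOWS
    trials = session.trials
    usable = []
    for bi, b in enumerate(session.blocks):
        n = b.end_trial - b.start_trial + 1
        if n < 2:
            log.warning("block %d (%s) has %d trial(s); skipped", bi, b.label, n)
            continue
        usable.append(bi)
    if len(usable) < 2:
        raise ValueError("block comparison needs at least 2 blocks "
                         "with >= 2 trials each")
    t = session.unit(unit_id).times
    anchor_of = {
        "VC_ON_PD": lambda tr: tr.vc_on_time,
        "RWD_PD": lambda tr: tr.rwd_pd_time,
        "RTN_PD": lambda tr: tr.rtn_pd_time,
    }
    out = {}
    for kind, w in windows.items():
        per_block = []
        for bi in usable:
            b = session.blocks[bi]
            anchors = np.array(
                [anchor_of[kind](tr)
                 for tr in trials[b.start_trial : b.end_trial + 1]]
            )
            rates = _counts_in_windows(t, anchors - w, w) / w
            per_block.append(rates)
        means = np.array([r.mean() for r in per_block])
        pairs, p_raw = [], []
        for i in range(len(per_block)):
            for j in range(i + 1, len(per_block)):
                res = stats.ttest_ind(
                    per_block[i], per_block[j], equal_var=False
                )
                pairs.append((i, j))
                p_raw.append(float(res.pvalue))
        p_raw = np.asarray(p_raw)
        p_adj = holm_adjust(np.nan_to_num(p_raw, nan=1.0))
        out[kind] = BlockComparisonResult(
            kind, usable, means, pairs, p_raw, p_adj,
            means[0] > means[1:],
        )
    return out
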