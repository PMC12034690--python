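"""Spike-train analyses of the LDS test.

Implements the intracollicular (ICC) analysis chain: spontaneous-rate binning,
afterdischarge calling against the PRE-rate 95% band, peristimulus time
histograms folded on the tone-pip cycle, tone-evoked rate and response-duration
metrics PRE vs. the first post-LDS train (T1), and the normalized plasticity
statistic delta = (POST - PRE) / (POST + PRE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ldstest.core import SpikeChannelRecording

__all__ = [
    "RateSeries",
    "AfterdischargeCall",
    "PSTH",
    "ToneResponseMetrics",
    "DeltaStat",
    "compute_bin_rates",
    "detect_afterdischarge",
    "afterdischarge_prevalence",
    "compute_psth",
    "tone_response_metrics",
    "delta",
    "lds_responsive",
]

DEFAULT_BIN_WIDTH_S = 2.5
ONSET_WINDOW_S = 30.0  # afterdischarges must start within 30 s of LDS offset
MIN_VALID_LATENCY_MS = 3.4  # tone responses starting earlier are artifacts


@dataclass
class RateSeries:
    """Firing rate in consecutive fixed-width bins (trailing partial bin
    discarded). ``bin_edges_s`` are relative to the epoch start."""

    bin_edges_s: np.ndarray
    rate_per_bin: np.ndarray
    bin_width_s: float

    @property
    def n_bins(self) -> int:
        return self.rate_per_bin.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.rate_per_bin))

    def sd(self, ddof: int = 1) -> float:
        return float(np.std(self.rate_per_bin, ddof=ddof))


@dataclass
class AfterdischargeCall:
    present: bool
    onset_time_s: float | None  # relative to LDS offset; None when absent
    upper_bound_rate: float  # criterion bound in events/s


@dataclass
class PSTH:
    """Mean spike count per bin per pip, folded on one pip cycle."""

    bin_edges_ms: np.ndarray
    mean_count_per_bin: np.ndarray
    n_pips: int
    cycle_ms: float

    @property
    def bin_rates(self) -> np.ndarray:
        """Per-bin rate in events/s (counts per pip / bin width)."""
        widths_s = np.diff(self.bin_edges_ms) / 1000.0
        return self.mean_count_per_bin / widths_s

    @property
    def overall_rate(self) -> float:
        """Rate over the entire cycle in events/s."""
        return float(self.mean_count_per_bin.sum() / (self.cycle_ms / 1000.0))


@dataclass
class ToneResponseMetrics:
    pre_rate: float
    post_rate: float
    onset_latency_ms: float | None
    response_duration_ms: float | None
    onset_t1_ms: float | None
    duration_t1_ms: float | None
    valid: bool
    responsive: bool


@dataclass
class DeltaStat:
    delta: float
    classification: str  # potentiated | suppressed | unchanged | not_computable

    @property
    def computable(self) -> bool:
        return self.classification != "not_computable"


def compute_bin_rates(recording: SpikeChannelRecording, epoch: str,
                      bin_width_s: float = DEFAULT_BIN_WIDTH_S) -> RateSeries:
    """Bin the spikes of one epoch into consecutive ``bin_width_s`` bins.

    The trailing partial bin is discarded so every reported rate covers a full
    bin. Raises if the epoch is unknown or shorter than one bin.
    """
    if epoch not in recording.schedule.epochs:
        raise ValueError(f"unknown epoch {epoch!r}")
    start, end = recording.schedule.epochs[epoch]
    duration = end - start
    if duration < bin_width_s:
        raise ValueError(f"epoch {epoch!r} shorter than one bin ({duration} s)")
    n_bins = int(np.floor(duration / bin_width_s))
    edges = start + bin_width_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(recording.spike_times_s, bins=edges)
    return RateSeries(
        bin_edges_s=edges - start,
        rate_per_bin=counts / bin_width_s,
        bin_width_s=bin_width_s,
    )


def rate_criterion_bound(pre: RateSeries, mode: str = "prediction_band",
                         z: float = 1.96) -> float:
    """Upper edge of the PRE-rate 95% band.

    ``prediction_band`` (default) compares individual POST bins against the
    spread of individual PRE bins: mean + z*SD. ``ci_of_mean`` uses the
    standard error instead (mean + z*SD/sqrt(n)); under that reading single
    noisy bins exceed the bound far more easily.
    """
    if pre.n_bins < 2:
        raise ValueError("need >= 2 PRE bins to estimate the rate band")
    if mode == "prediction_band":
        return pre.mean + z * pre.sd()
    if mode == "ci_of_mean":
        return pre.mean + z * pre.sd() / np.sqrt(pre.n_bins)
    raise ValueError(f"unknown mode {mode!r}")


def detect_afterdischarge(pre: RateSeries, post: RateSeries,
                          mode: str = "prediction_band",
                          min_run: int = 3,
                          onset_window_s: float = ONSET_WINDOW_S) -> AfterdischargeCall:
    """Call an afterdischarge from PRE/POST spontaneous rate series.

    Present iff at least ``min_run`` consecutive POST bins strictly exceed the
    PRE 95% band and the first bin of the first qualifying run starts within
    ``onset_window_s`` of LDS offset (POST bin edges are relative to offset).
    """
    if post.n_bins < min_run:
        raise ValueError(f"need >= {min_run} POST bins")
    bound = rate_criterion_bound(pre, mode=mode)
    above = post.rate_per_bin > bound  # strict: ties do not count
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run == min_run:
            onset = float(post.bin_edges_s[i - min_run + 1])
            if onset <= onset_window_s:
                return AfterdischargeCall(True, onset, bound)
            return AfterdischargeCall(False, None, bound)
    return AfterdischargeCall(False, None, bound)


def afterdischarge_prevalence(calls, labels) -> pd.DataFrame:
    """Fraction of afterdischarge-positive channels per group.

    Returns a frame with columns ``group, n, positives, proportion, percent``;
    counts are retained for two-sample proportions tests.
    """
    calls = list(calls)
    labels = list(labels)
    if len(calls) != len(labels):
        raise ValueError("calls and labels must have equal length")
    df = pd.DataFrame({
        "group": labels,
        "positive": [bool(c.present) for c in calls],
    })
    out = df.groupby("group", sort=True)["positive"].agg(n="size", positives="sum")
    if (out["n"] == 0).any():
        raise ValueError("empty group")
    out = out.reset_index()
    out["proportion"] = out["positives"] / out["n"]
    out["percent"] = 100.0 * out["proportion"]
    return out


def compute_psth(recording: SpikeChannelRecording, trains: str = "pre",
                 bin_width_ms: float = 0.5) -> PSTH:
    """Fold spikes onto the tone-pip cycle and average per pip.

    ``trains`` selects which pip trains to fold: ``"pre"`` (all 6 PRE trains),
    ``"t1"`` (first POST train) or ``"post"`` (all 6 POST trains). The cycle
    length is 1/pip_rate (~47.4 ms at 21.1 Hz); the last bin is shortened to
    end exactly at the cycle so spike counts are conserved.
    """
    sched = recording.schedule
    cycle_ms = 1000.0 * sched.pip_cycle_s
    if bin_width_ms > cycle_ms:
        raise ValueError(f"bin width {bin_width_ms} ms exceeds the {cycle_ms:.2f} ms cycle")
    if trains == "pre":
        groups = sched.pre_train_onsets
    elif trains == "post":
        groups = sched.post_train_onsets
    elif trains == "t1":
        groups = sched.post_train_onsets[:1]
    else:
        raise ValueError(f"unknown train selection {trains!r}")
    onsets = np.concatenate(groups) if groups else np.empty(0)
    if onsets.size == 0:
        raise ValueError("no pips in the selected trains")

    edges = np.arange(0.0, cycle_ms, bin_width_ms)
    edges = np.append(edges, cycle_ms)
    spikes = recording.spike_times_s * 1000.0  # ms
    # assign each spike to the preceding pip; keep those within one cycle
    onsets_ms = np.sort(onsets) * 1000.0
    idx = np.searchsorted(onsets_ms, spikes, side="right") - 1
    in_range = idx >= 0
    rel = spikes[in_range] - onsets_ms[idx[in_range]]
    rel = rel[rel < cycle_ms]
    counts, _ = np.histogram(rel, bins=edges)
    return PSTH(
        bin_edges_ms=edges,
        mean_count_per_bin=counts / onsets.size,
        n_pips=int(onsets.size),
        cycle_ms=cycle_ms,
    )


def _onset_and_duration(psth: PSTH, threshold: float, min_run: int = 2,
                        gap_tolerance: int = 1) -> tuple[float | None, float | None]:
    """First sustained supra-threshold crossing and the length of its run.

    Onset = left edge of the first bin whose rate exceeds ``threshold`` for at
    least ``min_run`` consecutive bins; the run then extends until more than
    ``gap_tolerance`` consecutive bins fall back below threshold. Duration is
    onset to the right edge of the run's last supra-threshold bin.
    """
    above = psth.bin_rates > threshold
    n = above.size
    start = None
    for i in range(n - min_run + 1):
        if all(above[i:i + min_run]):
            start = i
            break
    if start is None:
        return None, None
    last = start
    gap = 0
    for j in range(start, n):
        if above[j]:
            last = j
            gap = 0
        else:
            gap += 1
            if gap > gap_tolerance:
                break
    onset_ms = float(psth.bin_edges_ms[start])
    duration_ms = float(psth.bin_edges_ms[last + 1] - psth.bin_edges_ms[start])
    return onset_ms, duration_ms


def tone_response_metrics(psth_pre: PSTH, psth_t1: PSTH, spont: RateSeries,
                          threshold_sd: float = 2.0, min_run: int = 2,
                          gap_tolerance: int = 1,
                          min_valid_latency_ms: float = MIN_VALID_LATENCY_MS,
                          ) -> ToneResponseMetrics:
    """Tone-evoked rate and response-duration metrics, PRE vs. T1.

    The overall PRE rate is taken from the PSTH over the entire pip cycle
    across all six PRE trains; the POST rate from the T1 PSTH. Onset/duration
    are measured on each PSTH against the spontaneous threshold
    mean + ``threshold_sd``*SD of the 2.5-s spontaneous bins. A response is
    valid only when its onset falls after ``min_valid_latency_ms`` (earlier
    "responses" are stimulus artifacts); a channel is responsive when PRE or
    T1 overall rate exceeds the spontaneous threshold.
    """
    if psth_pre.bin_edges_ms.shape != psth_t1.bin_edges_ms.shape or \
            not np.allclose(psth_pre.bin_edges_ms, psth_t1.bin_edges_ms):
        raise ValueError("PRE and T1 PSTHs must share binning")
    if spont.n_bins < 2:
        raise ValueError("missing spontaneous statistics (need >= 2 bins)")
    threshold = spont.mean + threshold_sd * spont.sd()
    onset_pre, dur_pre = _onset_and_duration(psth_pre, threshold, min_run, gap_tolerance)
    onset_t1, dur_t1 = _onset_and_duration(psth_t1, threshold, min_run, gap_tolerance)
    pre_rate = psth_pre.overall_rate
    post_rate = psth_t1.overall_rate
    onset = onset_pre if onset_pre is not None else onset_t1
    valid = onset is not None and onset > min_valid_latency_ms
    responsive = (pre_rate > threshold) or (post_rate > threshold)
    return ToneResponseMetrics(
        pre_rate=pre_rate,
        post_rate=post_rate,
        onset_latency_ms=onset_pre,
        response_duration_ms=dur_pre,
        onset_t1_ms=onset_t1,
        duration_t1_ms=dur_t1,
        valid=valid,
        responsive=responsive,
    )


def lds_responsive(recording: SpikeChannelRecording,
                   spont: RateSeries | None = None,
                   threshold_sd: float = 2.0) -> bool:
    """Whether the channel shows a sound-driven response during the LDS
    (mean LDS rate above the spontaneous mean + SD band)."""
    if spont is None:
        spont = compute_bin_rates(recording, "PRE_silence")
    lds = compute_bin_rates(recording, "LDS", bin_width_s=spont.bin_width_s)
    return lds.mean > spont.mean + threshold_sd * spont.sd()


def delta(pre: float, post: float) -> DeltaStat:
    """Normalized plasticity statistic (POST - PRE) / (POST + PRE).

    Bounded in [-1, 1]; positive = potentiated, negative = suppressed, zero =
    unchanged. Undefined (flagged not-computable) when both rates are zero.
    """
    if pre < 0 or post < 0:
        raise ValueError("rates must be nonnegative")
    if pre + post == 0:
        return DeltaStat(float("nan"), "not_computable")
    d = (post - pre) / (post + pre)
    if d > 0:
        cls = "potentiated"
    elif d < 0:
        cls = "suppressed"
    else:
        cls = "unchanged"
    return DeltaStat(float(d), cls)
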