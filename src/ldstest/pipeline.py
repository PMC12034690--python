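"""End-to-end stages tying the modules into the two LDS-test pipelines:
the ICC spike pipeline and the ABR_LDS pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ldstest import abr, behavior, bootstrap, spikes
from ldstest.core import AASessionSet, ABRSweepSet, SpikeChannelRecording
from ldstest.io import RunConfig

__all__ = ["analyze_spike_channel", "analyze_spike_dataset", "analyze_abr_pair"]


def analyze_spike_channel(rec: SpikeChannelRecording,
                          config: RunConfig = RunConfig()) -> dict:
    """Full per-channel ICC analysis: afterdischarge call, tone-evoked
    PRE/T1 rates, delta, onsets/durations, validity and responsiveness."""
    pre = spikes.compute_bin_rates(rec, "PRE_silence", config.rate_bin_width_s)
    post = spikes.compute_bin_rates(rec, "POST_silence", config.rate_bin_width_s)
    call = spikes.detect_afterdischarge(pre, post, mode=config.ci_mode,
                                        onset_window_s=config.onset_window_s)
    psth_pre = spikes.compute_psth(rec, "pre", config.psth_bin_width_ms)
    psth_t1 = spikes.compute_psth(rec, "t1", config.psth_bin_width_ms)
    tone = spikes.tone_response_metrics(
        psth_pre, psth_t1, pre,
        min_valid_latency_ms=config.min_valid_latency_ms)
    d = spikes.delta(tone.pre_rate, tone.post_rate)
    def num(x):
        return np.nan if x is None else x

    return {
        "channel_id": rec.channel_id,
        "afterdischarge": call.present,
        "onset_s": num(call.onset_time_s),
        "pre_rate": tone.pre_rate,
        "post_rate": tone.post_rate,
        "delta": d.delta,
        "classification": d.classification,
        "onset_latency_ms": num(tone.onset_latency_ms),
        "duration_pre_ms": num(tone.response_duration_ms),
        "duration_t1_ms": num(tone.duration_t1_ms),
        "valid": tone.valid,
        "responsive": tone.responsive and spikes.lds_responsive(rec, pre),
    }


def analyze_spike_dataset(recordings: list[SpikeChannelRecording],
                          config: RunConfig = RunConfig()) -> pd.DataFrame:
    rows = [analyze_spike_channel(r, config) for r in recordings]
    return pd.DataFrame(rows)


def analyze_abr_pair(pre: ABRSweepSet, post: ABRSweepSet,
                     config: RunConfig = RunConfig()) -> dict:
    """ABR_LDS analysis of one PRE/POST recording pair: averaged + filtered
    waveforms, picked waves, wave metrics and the bootstrap R suite."""
    wf_pre = abr.bandpass(abr.average_sweeps(pre), *config.filter_band_hz)
    wf_post = abr.bandpass(abr.average_sweeps(post), *config.filter_band_hz)
    peaks_pre = abr.pick_peaks_auto(wf_pre, config.window_ms,
                                    prominence_frac=config.peak_prominence_frac)
    peaks_post = abr.pick_peaks_auto(wf_post, config.window_ms,
                                     prominence_frac=config.peak_prominence_frac)
    metrics = abr.wave_metrics(peaks_pre, peaks_post)
    boot = bootstrap.lds_correlation_suite(
        pre, post, window_ms=config.window_ms, n_iter=config.bootstrap_n_iter,
        seed=config.seed, filter_band=config.filter_band_hz,
        cross_mode=config.bootstrap_cross_mode)
    return {
        "waveform_pre": wf_pre,
        "waveform_post": wf_post,
        "peaks_pre": peaks_pre,
        "peaks_post": peaks_post,
        "metrics": metrics,
        "bootstrap": boot,
    }


def wave_metrics_frame(result: dict, **meta) -> pd.DataFrame:
    """Flatten one analyze_abr_pair result into a per-wave metrics table."""
    m = result["metrics"]
    rows = []
    for w in abr.WAVE_NAMES:
        d = m.deltas[w]
        rows.append({
            **meta,
            "wave": w,
            "amplitude_uv_pre": m.amplitude_pre_uv[w],
            "amplitude_uv_post": m.amplitude_post_uv[w],
            "latency_ms_pre": m.latency_pre_ms[w],
            "latency_ms_post": m.latency_post_ms[w],
            "delta": None if d is None else d.delta,
        })
    return pd.DataFrame(rows)


def classify_aa(sessions: AASessionSet, config: RunConfig = RunConfig()):
    profile = behavior.percent_correct(sessions)
    return behavior.classify_tinnitus(
        profile, alpha=config.alpha,
        exclude_dip_from_grand_mean=config.grand_mean_excludes_dip)
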