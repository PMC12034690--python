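"""ABR waveform processing.

Sweep averaging, zero-phase band-pass filtering (500–3,000 Hz), rule-based
picking of waves I–VI anchored on wave V ("the peak before the deepest
trough"), wave amplitude/latency metrics with inter-wave latencies and V/I,
V/III central-gain ratios, per-wave delta statistics, and the
ascending-series threshold midpoint rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ldstest.core import ABRSweepSet, ABRWaveform
from ldstest.spikes import DeltaStat, delta

__all__ = [
    "WavePick",
    "WavePeakSet",
    "WaveMetrics",
    "ThresholdResult",
    "average_sweeps",
    "bandpass",
    "pick_peaks_auto",
    "wave_metrics",
    "threshold_midpoint",
]

WAVE_NAMES = ("I", "II", "III", "IV", "V", "VI")
DEFAULT_WINDOW_MS = (2.0, 14.0)
DEFAULT_BAND_HZ = (500.0, 3000.0)


@dataclass
class WavePick:
    peak_time_ms: float
    peak_uv: float
    trough_time_ms: float
    trough_uv: float

    def __post_init__(self) -> None:
        if self.trough_time_ms <= self.peak_time_ms:
            raise ValueError("trough must follow the peak")

    @property
    def amplitude_uv(self) -> float:
        return abs(self.peak_uv - self.trough_uv)


@dataclass
class WavePeakSet:
    """Picked peaks/troughs per wave; absent waves are simply missing."""

    waves: dict[str, WavePick] = field(default_factory=dict)
    warning: str | None = None

    def __contains__(self, wave: str) -> bool:
        return wave in self.waves

    def __getitem__(self, wave: str) -> WavePick:
        return self.waves[wave]

    def get(self, wave: str):
        return self.waves.get(wave)

    def latency_ms(self, wave: str):
        p = self.waves.get(wave)
        return None if p is None else p.peak_time_ms

    def amplitude_uv(self, wave: str):
        p = self.waves.get(wave)
        return None if p is None else p.amplitude_uv


def average_sweeps(sweeps: ABRSweepSet) -> ABRWaveform:
    """Pointwise mean across sweeps, aligned to stimulus onset."""
    return ABRWaveform(
        time_ms=sweeps.time_ms,
        voltage_uv=sweeps.sweeps.mean(axis=0),
        sample_rate=sweeps.sample_rate,
    )


def bandpass(waveform: ABRWaveform, low_hz: float = DEFAULT_BAND_HZ[0],
             high_hz: float = DEFAULT_BAND_HZ[1]) -> ABRWaveform:
    """Zero-phase band-pass: 4th-order Butterworth run forward and backward.

    Zero-phase filtering never shifts the extremum of a time-symmetric pulse,
    which keeps picked latencies comparable PRE vs. POST.
    """
    nyq = waveform.sample_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for Nyquist {nyq:.0f} Hz")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass",
                        fs=waveform.sample_rate, output="sos")
    return ABRWaveform(
        time_ms=waveform.time_ms,
        voltage_uv=signal.sosfiltfilt(sos, waveform.voltage_uv),
        sample_rate=waveform.sample_rate,
        filter_band_hz=(low_hz, high_hz),
    )


def _local_extrema(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima/minima; plateaus resolve to their earliest sample."""
    dv = np.diff(v)
    nz = np.nonzero(dv)[0]
    s = np.sign(dv[nz])
    maxima, minima = [], []
    for k in range(len(s) - 1):
        if s[k] > 0 and s[k + 1] < 0:
            maxima.append(nz[k] + 1)
        elif s[k] < 0 and s[k + 1] > 0:
            minima.append(nz[k] + 1)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _prominence_filter(v: np.ndarray, idx: np.ndarray, floor: float) -> np.ndarray:
    if idx.size == 0 or floor <= 0:
        return idx
    prom = signal.peak_prominences(v, idx)[0]
    return idx[prom >= floor]


def _parabolic_vertex(t: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a sampled extremum with the parabola through its 3 neighbours."""
    if i < 1 or i > v.size - 2:
        return float(t[i]), float(v[i])
    denom = v[i - 1] - 2 * v[i] + v[i + 1]
    if denom == 0:
        return float(t[i]), float(v[i])
    dx = 0.5 * (v[i - 1] - v[i + 1]) / denom
    dt = t[i + 1] - t[i]
    v_ref = v[i] - 0.25 * (v[i - 1] - v[i + 1]) * dx
    return float(t[i] + dx * dt), float(v_ref)


def pick_peaks_auto(waveform: ABRWaveform,
                    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
                    manual_override: dict[str, WavePick] | None = None,
                    prominence_frac: float = 0.05) -> WavePeakSet:
    """Rule-based stand-in for manual ABR peak picking.

    Within ``window_ms``: the deepest trough is the window's global minimum;
    wave V is the last local maximum preceding it; waves IV…I are the next
    local maxima counted backwards from V; wave VI is the first local maximum
    after wave V's trough. Each wave's trough is the first local minimum after
    its peak; a wave without a qualifying peak or trough is absent. Candidate
    extrema must exceed ``prominence_frac`` of the window's peak-to-peak range
    to suppress noise ripples. ``manual_override`` replaces individual waves
    with explicit picks.
    """
    t, v = waveform.time_ms, waveform.voltage_uv
    lo, hi = window_ms
    if lo < t[0] or hi > t[-1]:
        raise ValueError(f"window {window_ms} outside waveform extent "
                         f"({t[0]:.2f}-{t[-1]:.2f} ms)")
    sel = np.nonzero((t >= lo) & (t <= hi))[0]
    vw = v[sel]
    # extrema and prominences on the full waveform (a wave near the window
    # edge would otherwise see its prominence truncated), candidates kept
    # only inside the window
    maxima, minima = _local_extrema(v)
    floor = prominence_frac * float(np.ptp(vw))
    maxima = _prominence_filter(v, maxima, floor)
    minima = _prominence_filter(-v, minima, floor)
    in_window = lambda idx: idx[(idx >= sel[0]) & (idx <= sel[-1])]  # noqa: E731
    maxima, minima = in_window(maxima), in_window(minima)

    result = WavePeakSet()
    if maxima.size == 0:
        result.warning = "no local maximum in picking window"
    else:
        deepest = int(sel[np.argmin(vw)])

        def first_trough_after(peak_i: int):
            after = minima[minima > peak_i]
            return int(after[0]) if after.size else None

        def make_pick(peak_i: int):
            trough_i = first_trough_after(peak_i)
            if trough_i is None:
                return None
            pt, pv = _parabolic_vertex(t, v, peak_i)
            tt, tv = _parabolic_vertex(t, v, trough_i)
            return WavePick(peak_time_ms=pt, peak_uv=pv,
                            trough_time_ms=tt, trough_uv=tv)

        before = maxima[maxima < deepest]
        if before.size:
            v_peak = int(before[-1])
            pick_v = make_pick(v_peak)
            if pick_v is not None:
                result.waves["V"] = pick_v
                # waves IV..I: successive maxima preceding V
                preceding = before[:-1]
                for j, wave in enumerate(("IV", "III", "II", "I")):
                    if j >= preceding.size:
                        break
                    p = make_pick(int(preceding[-1 - j]))
                    if p is not None:
                        result.waves[wave] = p
                # wave VI: first maximum after V's trough
                trough_v = first_trough_after(v_peak)
                after = maxima[maxima > trough_v] if trough_v is not None else np.empty(0, int)
                if after.size:
                    p = make_pick(int(after[0]))
                    if p is not None:
                        result.waves["VI"] = p
        if not result.waves:
            result.warning = "no pickable wave V in window"

    if manual_override:
        for wave, pick in manual_override.items():
            if wave not in WAVE_NAMES:
                raise ValueError(f"unknown wave {wave!r}")
            result.waves[wave] = pick
    return result


@dataclass
class WaveMetrics:
    """Per-wave amplitude/latency metrics for a PRE/POST waveform pair.

    ``deltas`` holds the normalized PRE/POST amplitude change per wave.
    Ratios or latencies whose operands are absent (or a zero denominator) are
    ``None`` — flagged not-computable rather than guessed.
    """

    amplitude_pre_uv: dict[str, float | None]
    amplitude_post_uv: dict[str, float | None]
    latency_pre_ms: dict[str, float | None]
    latency_post_ms: dict[str, float | None]
    deltas: dict[str, DeltaStat | None]
    interwave_pre_ms: dict[str, float | None]
    interwave_post_ms: dict[str, float | None]
    ratios_pre: dict[str, float | None]
    ratios_post: dict[str, float | None]


def _interwave(peaks: WavePeakSet) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for a, b, name in (("I", "V", "I-V"), ("I", "VI", "I-VI")):
        la, lb = peaks.latency_ms(a), peaks.latency_ms(b)
        out[name] = None if la is None or lb is None else lb - la
    return out


def _ratios(peaks: WavePeakSet) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for num, den, name in (("V", "I", "V/I"), ("V", "III", "V/III")):
        an, ad = peaks.amplitude_uv(num), peaks.amplitude_uv(den)
        out[name] = None if an is None or ad is None or ad == 0 else an / ad
    return out


def wave_metrics(pre_peaks: WavePeakSet, post_peaks: WavePeakSet) -> WaveMetrics:
    """Amplitudes, latencies, inter-wave latencies, central-gain ratios and
    per-wave delta statistics from PRE/POST peak sets."""
    amp_pre = {w: pre_peaks.amplitude_uv(w) for w in WAVE_NAMES}
    amp_post = {w: post_peaks.amplitude_uv(w) for w in WAVE_NAMES}
    deltas: dict[str, DeltaStat | None] = {}
    for w in WAVE_NAMES:
        a, b = amp_pre[w], amp_post[w]
        deltas[w] = None if a is None or b is None else delta(a, b)
    return WaveMetrics(
        amplitude_pre_uv=amp_pre,
        amplitude_post_uv=amp_post,
        latency_pre_ms={w: pre_peaks.latency_ms(w) for w in WAVE_NAMES},
        latency_post_ms={w: post_peaks.latency_ms(w) for w in WAVE_NAMES},
        deltas=deltas,
        interwave_pre_ms=_interwave(pre_peaks),
        interwave_post_ms=_interwave(post_peaks),
        ratios_pre=_ratios(pre_peaks),
        ratios_post=_ratios(post_peaks),
    )


@dataclass
class ThresholdResult:
    threshold_db: float
    censored: str | None  # None | "floor" | "ceiling"
    warning: str | None = None


def threshold_midpoint(levels_db, detected, step_db: float | None = None) -> ThresholdResult:
    """Hearing threshold from an ascending level series.

    Threshold = midpoint between the first level with a detectable response and
    the last level without one. Detection at the lowest tested level yields
    lowest - step/2 (floor-censored); no detection at any level yields
    highest + step/2 (ceiling-censored). A non-monotone profile (detected, then
    not, then detected) falls back to the lowest level above which every level
    is detected, with a warning.
    """
    levels = np.asarray(levels_db, dtype=float)
    det = np.asarray(detected, dtype=bool)
    if levels.size == 0:
        raise ValueError("need at least one tested level")
    if levels.size != det.size:
        raise ValueError("levels and detection flags must align")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be strictly increasing")
    if step_db is None:
        step_db = float(np.diff(levels)[0]) if levels.size > 1 else 5.0

    if not det.any():
        return ThresholdResult(float(levels[-1] + step_db / 2.0), "ceiling")

    first = int(np.argmax(det))
    warning = None
    if not det[first:].all():
        # non-monotone: lowest level above which all are detected
        warning = "non-monotone detection profile"
        first = len(det) - 1
        while first > 0 and det[first - 1]:
            first -= 1
    if first == 0:
        return ThresholdResult(float(levels[0] - step_db / 2.0), "floor", warning)
    return ThresholdResult(float((levels[first] + levels[first - 1]) / 2.0), None, warning)
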