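"""Synthetic LDS-test datasets.

Three generators emulate the study's recordings so every downstream stage is
testable without external data:

- multi-channel ICC spike trains: homogeneous Poisson spontaneous activity,
  onset-locked tone-pip responses, an optional sound-driven response during
  the LDS, and an optional exponentially decaying afterdischarge after LDS
  offset (all additive Poisson processes);
- ABR sweep sets: a six-wave biphasic template (difference of Gaussians per
  wave) plus white noise per sweep, with per-wave amplitude/latency modifiers
  for the POST condition;
- active-avoidance sessions: Bernoulli trial outcomes with an optional
  frequency-specific avoidance dip.

All randomness flows from one explicit seed per dataset; per-channel and
per-sweep substreams are derived deterministically from (seed, index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ldstest.core import AASessionSet, ABRSweepSet, EpochSchedule, SpikeChannelRecording

__all__ = [
    "AfterdischargeSpec",
    "ToneResponseSpec",
    "SpikeSimConfig",
    "WaveComponent",
    "ABRSimConfig",
    "AASimConfig",
    "build_schedule",
    "gen_spike_dataset",
    "gen_abr_dataset",
    "abr_template",
    "gen_aa_sessions",
]


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AfterdischargeSpec:
    """Planted afterdischarge: a rate increment of
    ``peak_rate_multiplier * spontaneous_rate * exp(-t/decay_tau_s)`` starting
    ``onset_delay_s`` after LDS offset."""

    present: bool = False
    onset_delay_s: float = 0.0
    peak_rate_multiplier: float = 5.0
    decay_tau_s: float = 20.0


@dataclass(frozen=True)
class ToneResponseSpec:
    """Onset-locked response to each tone pip.

    Evoked spikes are added as a constant-rate Poisson burst over
    ``[onset_latency_s, onset_latency_s + response_duration_s]`` after each pip
    onset. ``post_scale`` multiplies the evoked rate for post-LDS trains and is
    the knob that plants a plasticity effect (delta < 0 for post_scale < 1).
    """

    onset_latency_s: float = 0.006
    response_duration_s: float = 0.012
    evoked_rate: float = 100.0
    post_scale: float = 1.0


@dataclass(frozen=True)
class SpikeSimConfig:
    n_channels: int = 32
    spontaneous_rate: float = 5.0
    pre_duration_s: float = 60.0
    post_duration_s: float = 240.0
    lds_duration_s: float = 60.0
    afterdischarge: AfterdischargeSpec | tuple[AfterdischargeSpec, ...] = AfterdischargeSpec()
    tone_response: ToneResponseSpec = ToneResponseSpec()
    lds_evoked_rate: float = 20.0
    pip_rate_hz: float = 21.1
    n_trains: int = 6
    train_duration_s: float = 10.0
    train_gap_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.spontaneous_rate < 0:
            raise ValueError("spontaneous_rate must be >= 0")
        for name in ("pre_duration_s", "post_duration_s", "lds_duration_s",
                     "train_duration_s", "train_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pip_rate_hz <= 0:
            raise ValueError("pip_rate_hz must be > 0")
        if self.lds_evoked_rate < 0:
            raise ValueError("lds_evoked_rate must be >= 0")
        tr = self.tone_response
        if tr.onset_latency_s < 0:
            raise ValueError("tone_response.onset_latency_s must be >= 0")
        if tr.response_duration_s <= 0:
            raise ValueError("tone_response.response_duration_s must be > 0")
        if tr.evoked_rate < 0:
            raise ValueError("tone_response.evoked_rate must be >= 0")
        if tr.post_scale < 0:
            raise ValueError("tone_response.post_scale must be >= 0")
        for ad in self._ad_specs():
            if ad.onset_delay_s < 0:
                raise ValueError("afterdischarge.onset_delay_s must be >= 0")
            if ad.present and ad.peak_rate_multiplier <= 1:
                raise ValueError("afterdischarge.peak_rate_multiplier must be > 1")
            if ad.decay_tau_s <= 0:
                raise ValueError("afterdischarge.decay_tau_s must be > 0")

    def _ad_specs(self) -> tuple[AfterdischargeSpec, ...]:
        ad = self.afterdischarge
        if isinstance(ad, AfterdischargeSpec):
            return (ad,) * self.n_channels
        ad = tuple(ad)
        if len(ad) != self.n_channels:
            raise ValueError(
                "afterdischarge: need one spec per channel "
                f"({len(ad)} given, {self.n_channels} channels)"
            )
        return ad


def build_schedule(config: SpikeSimConfig) -> EpochSchedule:
    """Lay out one LDS-test run on a single timeline.

    Order: PRE tone trains, PRE silence, LDS, POST silence, POST tone trains.
    POST silence starts at LDS offset so afterdischarge onsets are measured
    from 0 within it; T1 is the first POST train regardless of its wall-clock
    position (the generator injects post-LDS plasticity explicitly).
    """
    period = config.train_duration_s + config.train_gap_s
    pips_per_train = int(np.floor(config.train_duration_s * config.pip_rate_hz))
    k = np.arange(pips_per_train) / config.pip_rate_hz

    t = 0.0
    pre_trains = []
    for _ in range(config.n_trains):
        pre_trains.append(t + k)
        t += period
    pre_sil = (t, t + config.pre_duration_s)
    t = pre_sil[1]
    lds = (t, t + config.lds_duration_s)
    t = lds[1]
    post_sil = (t, t + config.post_duration_s)
    t = post_sil[1]
    post_trains = []
    for _ in range(config.n_trains):
        post_trains.append(t + k)
        t += period
    return EpochSchedule(
        epochs={"PRE_silence": pre_sil, "LDS": lds, "POST_silence": post_sil},
        pre_train_onsets=pre_trains,
        post_train_onsets=post_trains,
        pip_rate_hz=config.pip_rate_hz,
    )


def _homogeneous_poisson(rng: np.random.Generator, rate: float,
                         start: float, end: float) -> np.ndarray:
    if rate <= 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate * (end - start))
    return rng.uniform(start, end, n)


def _pip_evoked(rng: np.random.Generator, onsets: np.ndarray,
                spec: ToneResponseSpec, scale: float) -> np.ndarray:
    lam = spec.evoked_rate * scale * spec.response_duration_s
    if lam <= 0 or onsets.size == 0:
        return np.empty(0)
    counts = rng.poisson(lam, onsets.size)
    base = np.repeat(onsets + spec.onset_latency_s, counts)
    return base + rng.uniform(0.0, spec.response_duration_s, base.size)


def _afterdischarge_spikes(rng: np.random.Generator, ad: AfterdischargeSpec,
                           spont_rate: float, lds_offset: float,
                           horizon: float) -> np.ndarray:
    """Inhomogeneous Poisson with rate m*r0*exp(-t/tau) from onset, by inversion."""
    peak = ad.peak_rate_multiplier * spont_rate
    t0 = lds_offset + ad.onset_delay_s
    span = horizon - t0
    if peak <= 0 or span <= 0:
        return np.empty(0)
    tau = ad.decay_tau_s
    total = peak * tau * (1.0 - np.exp(-span / tau))
    n = rng.poisson(total)
    u = rng.uniform(0.0, 1.0 - np.exp(-span / tau), n)
    return t0 - tau * np.log1p(-u)


def gen_spike_dataset(config: SpikeSimConfig) -> list[SpikeChannelRecording]:
    """Simulate one multi-channel LDS-test spike recording.

    Per channel: spontaneous homogeneous Poisson over the whole run, an added
    constant rate during the LDS, onset-locked pip responses (post trains
    scaled by ``post_scale``), and, where specified, an afterdischarge rate
    increment decaying exponentially after LDS offset. Deterministic under
    ``config.seed`` (channel index mixed into the seed).
    """
    config.validate()
    sched = build_schedule(config)
    ad_specs = config._ad_specs()
    lds_start, lds_end = sched.epochs["LDS"]
    post_sil_end = sched.epochs["POST_silence"][1]
    total = sched.post_train_onsets[-1][-1] + 1.0 / config.pip_rate_hz \
        + config.train_gap_s if config.n_trains else post_sil_end

    recordings = []
    for ch in range(config.n_channels):
        rng = np.random.default_rng([config.seed, ch])
        parts = [_homogeneous_poisson(rng, config.spontaneous_rate, 0.0, total)]
        parts.append(_homogeneous_poisson(rng, config.lds_evoked_rate, lds_start, lds_end))
        for onsets in sched.pre_train_onsets:
            parts.append(_pip_evoked(rng, onsets, config.tone_response, 1.0))
        for onsets in sched.post_train_onsets:
            parts.append(_pip_evoked(rng, onsets, config.tone_response,
                                     config.tone_response.post_scale))
        if ad_specs[ch].present:
            parts.append(_afterdischarge_spikes(
                rng, ad_specs[ch], config.spontaneous_rate, lds_end, post_sil_end))
        spikes = np.sort(np.concatenate(parts))
        recordings.append(SpikeChannelRecording(ch, spikes, sched))
    return recordings


# ---------------------------------------------------------------------------
# ABR sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveComponent:
    """One biphasic ABR wave: positive Gaussian lobe at ``latency_ms`` followed
    by a negative lobe (``trough_fraction`` of the amplitude) delayed by
    ``trough_delay_sigma`` standard deviations. ``width_ms`` is the Gaussian
    sigma of both lobes."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float = 0.20


# Mouse-like defaults: wave V dominant so its following trough is the global
# minimum of the waveform, anchoring the picking rule.
DEFAULT_WAVE_TEMPLATE = (
    WaveComponent(2.2, 0.70),
    WaveComponent(3.0, 0.60),
    WaveComponent(3.9, 0.65),
    WaveComponent(4.9, 0.55),
    WaveComponent(6.0, 1.40),
    WaveComponent(7.4, 0.50),
)


@dataclass(frozen=True)
class PostModifier:
    amplitude_scale: float = 1.0
    latency_shift_ms: float = 0.0


@dataclass(frozen=True)
class ABRSimConfig:
    sample_rate: float = 25_000.0
    window_ms: float = 15.0
    wave_template: tuple[WaveComponent, ...] = DEFAULT_WAVE_TEMPLATE
    n_sweeps: int = 1266
    noise_sd_uv: float = 1.0
    post_modifiers: tuple[PostModifier, ...] = (PostModifier(),) * 6
    trough_fraction: float = 0.7
    trough_delay_sigma: float = 2.2
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.n_sweeps < 2:
            raise ValueError("n_sweeps must be >= 2")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        lats = [w.latency_ms for w in self.wave_template]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("wave_template latencies must be strictly increasing")
        if any(w.width_ms <= 0 for w in self.wave_template):
            raise ValueError("wave_template widths must be > 0")
        if len(self.post_modifiers) != len(self.wave_template):
            raise ValueError("post_modifiers: need one per wave")


def abr_template(config: ABRSimConfig, t_ms: np.ndarray,
                 post: bool = False) -> np.ndarray:
    """Evaluate the noise-free waveform template at times ``t_ms``."""
    t = np.asarray(t_ms, dtype=float)
    v = np.zeros_like(t)
    for i, w in enumerate(config.wave_template):
        amp, lat = w.amplitude_uv, w.latency_ms
        if post:
            amp *= config.post_modifiers[i].amplitude_scale
            lat += config.post_modifiers[i].latency_shift_ms
        s = w.width_ms
        v += amp * (np.exp(-((t - lat) ** 2) / (2 * s * s))
                    - config.trough_fraction
                    * np.exp(-((t - lat - config.trough_delay_sigma * s) ** 2) / (2 * s * s)))
    return v


def gen_abr_dataset(config: ABRSimConfig) -> tuple[ABRSweepSet, ABRSweepSet]:
    """Simulate (PRE, POST) sweep sets: template + white noise per sweep."""
    config.validate()
    n_samples = int(round(config.window_ms / 1000.0 * config.sample_rate))
    t_ms = np.arange(n_samples) / config.sample_rate * 1000.0
    rng = np.random.default_rng(config.seed)
    sets = []
    for post in (False, True):
        tmpl = abr_template(config, t_ms, post=post)
        noise = rng.normal(0.0, config.noise_sd_uv, (config.n_sweeps, n_samples)) \
            if config.noise_sd_uv > 0 else np.zeros((config.n_sweeps, n_samples))
        sets.append(ABRSweepSet(
            sweeps=tmpl[None, :] + noise,
            sample_rate=config.sample_rate,
            condition="POST" if post else "PRE",
            metadata=dict(config.metadata),
        ))
    return sets[0], sets[1]


# ---------------------------------------------------------------------------
# active avoidance
# ---------------------------------------------------------------------------

def quarter_octave_frequencies(lo_khz: float = 9.0, hi_khz: float = 36.0,
                               step_octaves: float = 0.25) -> np.ndarray:
    """Tone grid used in the shuttle-box task (9–36 kHz, 1/4-octave steps)."""
    n = int(round(np.log2(hi_khz / lo_khz) / step_octaves))
    return lo_khz * 2.0 ** (step_octaves * np.arange(n + 1))


@dataclass(frozen=True)
class AASimConfig:
    frequencies: tuple[float, ...] = tuple(np.round(quarter_octave_frequencies(), 3))
    n_sessions: int = 5
    trials_per_session_per_frequency: int = 8
    baseline_avoid_prob: float = 0.85
    dip_frequency: float | None = None
    dip_avoid_prob: float = 0.40
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.baseline_avoid_prob <= 1.0:
            raise ValueError("baseline_avoid_prob must be in [0, 1]")
        if not 0.0 <= self.dip_avoid_prob <= 1.0:
            raise ValueError("dip_avoid_prob must be in [0, 1]")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.trials_per_session_per_frequency < 1:
            raise ValueError("trials_per_session_per_frequency must be >= 1")
        if self.dip_frequency is not None and self.dip_frequency not in self.frequencies:
            raise ValueError("dip_frequency must be one of frequencies")


def gen_aa_sessions(config: AASimConfig, animal_id: str = "synthetic") -> AASessionSet:
    """Simulate one animal's avoidance sessions: Bernoulli trials per
    (session, frequency) cell at the frequency's avoid probability."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.frequencies, float)
    probs = np.full(freqs.size, config.baseline_avoid_prob)
    if config.dip_frequency is not None:
        probs[freqs == config.dip_frequency] = config.dip_avoid_prob
    m = config.trials_per_session_per_frequency
    n_s = config.n_sessions
    outcomes = rng.random((n_s, freqs.size, m)) < probs[None, :, None]
    trials = pd.DataFrame({
        "session": np.repeat(np.arange(1, n_s + 1), freqs.size * m),
        "frequency_khz": np.tile(np.repeat(freqs, m), n_s),
        "avoided": outcomes.reshape(-1).astype(int),
    })
    return AASessionSet(trials=trials, animal_id=animal_id)


def with_seed(config, seed: int):
    """Return a copy of any generator config with a new seed."""
    return replace(config, seed=seed)
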