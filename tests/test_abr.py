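"""ABR processing: averaging, filtering, peak picking, metrics, thresholds."""

import numpy as np
import pytest

from ldstest.abr import (
    WAVE_NAMES,
    WavePick,
    average_sweeps,
    bandpass,
    pick_peaks_auto,
    threshold_midpoint,
    wave_metrics,
)
from ldstest.core import ABRSweepSet, ABRWaveform
from ldstest.synth import ABRSimConfig, abr_template, gen_abr_dataset


def waveform_from(v, fs=25_000.0):
    v = np.asarray(v, float)
    return ABRWaveform(np.arange(v.size) / fs * 1000.0, v, fs)


class TestAveraging:
    def test_identical_sweeps_average_to_any_sweep(self):
        v = np.sin(np.linspace(0, 4 * np.pi, 375))
        s = ABRSweepSet(np.tile(v, (5, 1)), 25_000.0, "PRE")
        assert np.allclose(average_sweeps(s).voltage_uv, v, rtol=0, atol=1e-15)

    def test_symmetric_noise_cancels(self):
        v = np.sin(np.linspace(0, 4 * np.pi, 375))
        eps = np.random.default_rng(0).normal(0, 1, 375)
        s = ABRSweepSet(np.stack([v + eps, v - eps]), 25_000.0, "PRE")
        assert np.allclose(average_sweeps(s).voltage_uv, v, atol=1e-12)

    def test_linearity_in_sweep_scaling(self, rng):
        mat = rng.normal(size=(8, 100))
        s1 = ABRSweepSet(mat, 25_000.0, "PRE")
        s2 = ABRSweepSet(3.0 * mat, 25_000.0, "PRE")
        assert np.allclose(average_sweeps(s2).voltage_uv,
                           3.0 * average_sweeps(s1).voltage_uv)

    def test_residual_noise_shrinks_like_clt(self):
        # sd 1 uV over 1,266 sweeps: max |avg - template| < 5/sqrt(1266)
        # in >= 95% of 100 seeds
        hits = 0
        for seed in range(100):
            cfg = ABRSimConfig(n_sweeps=1266, noise_sd_uv=1.0, seed=seed)
            pre, _ = gen_abr_dataset(cfg)
            tmpl = abr_template(cfg, pre.time_ms)
            resid = np.abs(average_sweeps(pre).voltage_uv - tmpl).max()
            hits += resid < 5.0 / np.sqrt(1266)
        assert hits >= 95


class TestBandpass:
    def test_passband_tone_preserved(self):
        fs = 25_000.0
        t = np.arange(int(fs * 0.1)) / fs
        wf = waveform_from(np.sin(2 * np.pi * 1500 * t), fs)
        out = bandpass(wf).voltage_uv[200:-200]  # avoid edge transients
        assert np.abs(out).max() > 0.99

    def test_stopband_tone_removed(self):
        fs = 25_000.0
        t = np.arange(int(fs * 0.5)) / fs
        wf = waveform_from(np.sin(2 * np.pi * 50 * t), fs)
        out = bandpass(wf).voltage_uv[2000:-2000]
        assert np.abs(out).max() < 0.05

    def test_zero_phase_keeps_symmetric_pulse_centered(self):
        fs = 25_000.0
        t = np.arange(500) / fs * 1000.0
        pulse = np.exp(-((t - 10.0) ** 2) / (2 * 0.2 ** 2))
        out = bandpass(waveform_from(pulse, fs))
        assert np.argmax(out.voltage_uv) == np.argmax(pulse)

    def test_band_above_nyquist_rejected(self):
        wf = waveform_from(np.zeros(100), fs=4000.0)
        with pytest.raises(ValueError, match="band"):
            bandpass(wf, 500.0, 3000.0)


class TestPeakPicker:
    def test_recovers_six_waves_on_default_template(self, noise_free_abr_config):
        pre, _ = gen_abr_dataset(noise_free_abr_config)
        picks = pick_peaks_auto(average_sweeps(pre))
        assert set(picks.waves) == set(WAVE_NAMES)
        lats = [picks[w].peak_time_ms for w in WAVE_NAMES]
        assert all(b > a for a, b in zip(lats, lats[1:]))
        for w, ref in zip(WAVE_NAMES, noise_free_abr_config.wave_template):
            assert picks[w].peak_time_ms == pytest.approx(ref.latency_ms, abs=0.1)
            assert picks[w].trough_time_ms > picks[w].peak_time_ms

    def test_single_lobe_is_wave_v_only(self):
        fs = 25_000.0
        t = np.arange(375) / fs * 1000.0
        v = np.exp(-((t - 6.0) ** 2) / (2 * 0.2 ** 2)) \
            - 0.8 * np.exp(-((t - 6.6) ** 2) / (2 * 0.2 ** 2))
        picks = pick_peaks_auto(waveform_from(v, fs))
        assert "V" in picks.waves
        assert all(w not in picks.waves for w in ("I", "II", "III", "IV"))

    def test_flat_waveform_yields_warning(self):
        picks = pick_peaks_auto(waveform_from(np.zeros(375)))
        assert not picks.waves and picks.warning is not None

    def test_manual_override_replaces_single_wave(self, noise_free_abr_config):
        pre, _ = gen_abr_dataset(noise_free_abr_config)
        wf = average_sweeps(pre)
        auto = pick_peaks_auto(wf)
        override = WavePick(2.5, 1.5, 3.0, -0.5)
        picked = pick_peaks_auto(wf, manual_override={"I": override})
        assert picked["I"] is override
        for w in ("II", "III", "IV", "V", "VI"):
            assert picked[w].peak_time_ms == auto[w].peak_time_ms

    def test_override_with_automatic_picks_is_idempotent(self, noise_free_abr_config):
        pre, _ = gen_abr_dataset(noise_free_abr_config)
        wf = average_sweeps(pre)
        auto = pick_peaks_auto(wf)
        again = pick_peaks_auto(wf, manual_override=dict(auto.waves))
        assert {w: (p.peak_time_ms, p.trough_time_ms) for w, p in again.waves.items()} \
            == {w: (p.peak_time_ms, p.trough_time_ms) for w, p in auto.waves.items()}

    def test_window_outside_extent_rejected(self, noise_free_abr_config):
        pre, _ = gen_abr_dataset(noise_free_abr_config)
        with pytest.raises(ValueError, match="window"):
            pick_peaks_auto(average_sweeps(pre), window_ms=(2.0, 99.0))


class TestWaveMetrics:
    def _peaks(self, amp_v=1.0):
        waves = {
            "I": WavePick(2.2, 0.9, 2.7, -0.3),
            "III": WavePick(3.9, 0.8, 4.4, -0.2),
            "V": WavePick(6.0, amp_v, 6.6, amp_v - 1.4),
            "VI": WavePick(7.4, 0.4, 7.9, -0.1),
        }
        from ldstest.abr import WavePeakSet
        return WavePeakSet(waves=dict(waves))

    def test_identical_pre_post_all_deltas_zero(self):
        m = wave_metrics(self._peaks(), self._peaks())
        for w in ("I", "III", "V", "VI"):
            assert m.deltas[w].delta == 0.0

    def test_halved_wave_v_delta_is_minus_one_third(self):
        pre = self._peaks(1.0)  # amplitude 1.4
        post = self._peaks()
        post.waves["V"] = WavePick(6.0, 0.5, 6.6, -0.2)  # amplitude 0.7
        m = wave_metrics(pre, post)
        assert m.deltas["V"].delta == pytest.approx(-1.0 / 3.0)
        assert m.deltas["I"].delta == 0.0

    def test_amplitude_and_latency_arithmetic(self):
        from ldstest.abr import WavePeakSet
        pk = WavePeakSet(waves={"V": WavePick(5.0, 1.0, 5.6, -0.4)})
        m = wave_metrics(pk, pk)
        assert m.amplitude_pre_uv["V"] == pytest.approx(1.4)
        assert m.latency_pre_ms["V"] == 5.0

    def test_interwave_latencies_and_ratios(self):
        m = wave_metrics(self._peaks(), self._peaks())
        assert m.interwave_pre_ms["I-V"] == pytest.approx(3.8)
        assert m.interwave_pre_ms["I-VI"] == pytest.approx(5.2)
        assert m.ratios_pre["V/I"] == pytest.approx(1.4 / 1.2)
        assert m.ratios_pre["V/III"] == pytest.approx(1.4 / 1.0)

    def test_missing_wave_flags_not_computable(self):
        from ldstest.abr import WavePeakSet
        pk = WavePeakSet(waves={"V": WavePick(6.0, 1.0, 6.6, -0.4)})
        m = wave_metrics(pk, pk)
        assert m.deltas["I"] is None
        assert m.interwave_pre_ms["I-V"] is None
        assert m.ratios_pre["V/I"] is None


class TestThresholdMidpoint:
    def test_bracketing_pair_midpoint(self):
        levels = [30, 35, 40, 45]
        res = threshold_midpoint(levels, [False, False, True, True])
        assert res.threshold_db == 37.5 and res.censored is None

    def test_detected_at_floor_is_censored(self):
        res = threshold_midpoint([30, 35, 40], [True, True, True])
        assert res.threshold_db == 27.5 and res.censored == "floor"

    def test_never_detected_is_ceiling_censored(self):
        res = threshold_midpoint([80, 85, 90], [False, False, False])
        assert res.threshold_db == 92.5 and res.censored == "ceiling"

    def test_non_monotone_profile_uses_stable_detection(self):
        res = threshold_midpoint([30, 35, 40, 45, 50],
                                 [False, True, False, True, True])
        assert res.threshold_db == 42.5
        assert res.warning is not None

    def test_exclusion_flag_above_50db(self):
        # cohort filter: animals with thresholds > 50 dB SPL are excluded
        res = threshold_midpoint([40, 45, 50, 55, 60],
                                 [False, False, False, False, True])
        assert res.threshold_db > 50


class TestTemplateRecoveryAcrossDraws:
    def test_latencies_and_amplitudes_recovered_on_random_templates(self, rng):
        # noise-free templates, 100 random valid parameter draws:
        # latency within 1 sample, amplitude within 1% of the analytic value
        from ldstest.synth import WaveComponent
        base_lat = np.array([2.2, 3.0, 3.9, 4.9, 6.0, 7.4])
        n_ok = 0
        draws = 0
        while n_ok < 100 and draws < 1000:
            draws += 1
            lats = base_lat + rng.uniform(-0.1, 0.1, 6)
            amps = np.array([0.7, 0.6, 0.65, 0.55, 1.4, 0.5]) * rng.uniform(0.85, 1.15, 6)
            widths = rng.uniform(0.16, 0.21, 6)
            cfg = ABRSimConfig(
                n_sweeps=4, noise_sd_uv=0.0, seed=0,
                wave_template=tuple(WaveComponent(l, a, w)
                                    for l, a, w in zip(lats, amps, widths)))
            # validity: wave V's trough must be the template's global minimum
            tf = np.arange(2.0, 14.0, 0.001)
            vf = abr_template(cfg, tf)
            tmin = tf[np.argmin(vf)]
            if not (lats[4] < tmin < lats[5]):
                continue
            n_ok += 1
            pre, _ = gen_abr_dataset(cfg)
            picks = pick_peaks_auto(average_sweeps(pre))
            assert set(picks.waves) == set(WAVE_NAMES)
            dt = 1000.0 / cfg.sample_rate
            # analytic extrema of the summed template on the fine grid
            dv = np.diff(vf)
            fine_max = np.nonzero((dv[:-1] > 0) & (dv[1:] < 0))[0] + 1
            fine_min = np.nonzero((dv[:-1] < 0) & (dv[1:] > 0))[0] + 1
            for w in WAVE_NAMES:
                p = picks[w]
                pk = fine_max[np.argmin(np.abs(tf[fine_max] - p.peak_time_ms))]
                tr = fine_min[np.argmin(np.abs(tf[fine_min] - p.trough_time_ms))]
                assert abs(p.peak_time_ms - tf[pk]) <= dt + 1e-9
                analytic_amp = abs(vf[pk] - vf[tr])
                assert p.amplitude_uv == pytest.approx(analytic_amp, rel=0.01)
        assert n_ok == 100
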