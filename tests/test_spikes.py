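"""Spike-train analyses: binning, afterdischarge rule, PSTH, tone metrics, delta."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ldstest.core import EpochSchedule, SpikeChannelRecording
from ldstest.spikes import (
    RateSeries,
    afterdischarge_prevalence,
    compute_bin_rates,
    compute_psth,
    delta,
    detect_afterdischarge,
    rate_criterion_bound,
    tone_response_metrics,
)
from ldstest.synth import SpikeSimConfig, ToneResponseSpec, build_schedule, gen_spike_dataset


def make_recording(spike_times, pip_rate=21.1, n_trains=6):
    sched = build_schedule(SpikeSimConfig(pip_rate_hz=pip_rate, n_trains=n_trains))
    return SpikeChannelRecording(0, np.asarray(spike_times, float), sched)


def rate_series(rates, width=2.5):
    rates = np.asarray(rates, float)
    return RateSeries(width * np.arange(rates.size + 1), rates, width)


class TestBinRates:
    def test_constant_spacing_gives_constant_rate(self):
        sched = build_schedule(SpikeSimConfig())
        a, b = sched.epochs["PRE_silence"]
        # 4 spikes per 2.5 s -> 1.6 events/s in each of 24 bins
        times = a + np.arange(4 * 24) * (2.5 / 4) + 0.1
        rec = SpikeChannelRecording(0, times[times < b], sched)
        rs = compute_bin_rates(rec, "PRE_silence")
        assert rs.n_bins == 24
        assert np.allclose(rs.rate_per_bin, 1.6)

    def test_empty_epoch_gives_zero_rates(self):
        rec = make_recording([])
        rs = compute_bin_rates(rec, "POST_silence")
        assert rs.n_bins == 96 and (rs.rate_per_bin == 0).all()

    def test_unknown_epoch_named_in_error(self):
        rec = make_recording([])
        with pytest.raises(ValueError, match="nonexistent"):
            compute_bin_rates(rec, "nonexistent")

    def test_trailing_partial_bin_discarded(self):
        rec = make_recording([])
        rs = compute_bin_rates(rec, "PRE_silence", bin_width_s=7.0)
        assert rs.n_bins == 8  # floor(60 / 7)

    def test_seeded_poisson_mean_within_3se(self):
        cfg = SpikeSimConfig(n_channels=1, spontaneous_rate=10.0,
                             lds_evoked_rate=0.0,
                             tone_response=ToneResponseSpec(evoked_rate=0.0), seed=2)
        rec = gen_spike_dataset(cfg)[0]
        rs = compute_bin_rates(rec, "PRE_silence")
        se = np.sqrt(10.0 / (rs.n_bins * rs.bin_width_s))
        assert abs(rs.mean - 10.0) < 3 * se


class TestAfterdischargeRule:
    def test_identical_pre_post_is_absent(self):
        # PRE bins all equal (SD = 0): nothing strictly exceeds the mean
        pre = rate_series([5.0] * 24)
        post = rate_series([5.0] * 96)
        call = detect_afterdischarge(pre, post)
        assert not call.present and call.onset_time_s is None

    def test_step_at_offset_detected_with_onset_zero(self):
        rng = np.random.default_rng(123)
        pre = rate_series(rng.poisson(5 * 2.5, 24) / 2.5)
        post_rates = rng.poisson(5 * 2.5, 96) / 2.5
        post_rates[:8] = rng.poisson(25 * 2.5, 8) / 2.5  # 20-s step from offset
        call = detect_afterdischarge(pre, rate_series(post_rates))
        # hand-evaluate the rule on the same bins
        bound = pre.mean + 1.96 * pre.sd()
        assert (post_rates[:3] > bound).all()
        assert call.present and call.onset_time_s == 0.0
        assert call.upper_bound_rate == pytest.approx(bound)

    def test_step_after_onset_window_is_absent(self):
        rng = np.random.default_rng(123)
        pre = rate_series(rng.poisson(5 * 2.5, 24) / 2.5)
        post_rates = rng.poisson(5 * 2.5, 96) / 2.5
        post_rates[16:24] = rng.poisson(25 * 2.5, 8) / 2.5  # starts 40 s after offset
        call = detect_afterdischarge(pre, rate_series(post_rates))
        assert not call.present

    def test_two_bin_excursions_do_not_qualify(self):
        pre = rate_series([5, 6, 5, 4, 5, 6, 4, 5])
        bound = rate_criterion_bound(pre)
        post = np.full(96, 5.0)
        post[4:6] = bound + 10  # only 2 consecutive bins
        assert not detect_afterdischarge(pre, rate_series(post)).present

    def test_ci_of_mean_reading_is_more_liberal(self):
        pre = rate_series([5, 6, 5, 4, 5, 6, 4, 5])
        assert rate_criterion_bound(pre, "ci_of_mean") < rate_criterion_bound(pre)

    def test_too_few_post_bins_rejected(self):
        with pytest.raises(ValueError):
            detect_afterdischarge(rate_series([5, 5, 5]), rate_series([5, 5]))


class TestPrevalence:
    def test_counts_and_percent(self):
        calls = [detect_afterdischarge(rate_series([5.0] * 8 + [6.0] * 4),
                                       rate_series(r))
                 for r in ([np.full(96, 5.0)] * 84 +
                           [np.concatenate([np.full(3, 50.0), np.full(93, 5.0)])] * 16)]
        prev = afterdischarge_prevalence(calls, ["g"] * 100)
        assert prev.loc[0, "positives"] == 16 and prev.loc[0, "percent"] == 16.0

    def test_planted_prevalence_recovered(self):
        from ldstest.synth import AfterdischargeSpec
        n, planted = 500, 0.30
        specs = tuple(AfterdischargeSpec(i < planted * n, 0.0, 8.0, 20.0)
                      for i in range(n))
        cfg = SpikeSimConfig(n_channels=n, spontaneous_rate=5.0,
                             lds_evoked_rate=0.0,
                             tone_response=ToneResponseSpec(evoked_rate=0.0),
                             afterdischarge=specs, seed=21)
        recs = gen_spike_dataset(cfg)
        calls = [detect_afterdischarge(compute_bin_rates(r, "PRE_silence"),
                                       compute_bin_rates(r, "POST_silence"))
                 for r in recs]
        prev = afterdischarge_prevalence(calls, ["g"] * n)
        # estimate within the binomial 99% interval around 30% (n = 500)
        from scipy import stats as sps
        lo, hi = sps.binom.interval(0.99, n, planted)
        assert lo <= prev.loc[0, "positives"] <= hi


class TestPSTH:
    def test_single_latency_concentrates_mass(self):
        sched = build_schedule(SpikeSimConfig())
        onsets = np.concatenate(sched.pre_train_onsets)
        rec = SpikeChannelRecording(0, np.sort(onsets + 0.0052), sched)
        psth = compute_psth(rec, "pre", bin_width_ms=0.5)
        k = np.searchsorted(psth.bin_edges_ms, 5.2, side="right") - 1
        assert psth.mean_count_per_bin[k] == pytest.approx(1.0)
        assert psth.mean_count_per_bin.sum() == pytest.approx(1.0)

    def test_count_conservation(self):
        cfg = SpikeSimConfig(n_channels=1, spontaneous_rate=20.0, seed=6)
        rec = gen_spike_dataset(cfg)[0]
        sched = rec.schedule
        psth = compute_psth(rec, "t1", bin_width_ms=0.5)
        onsets = np.sort(sched.post_train_onsets[0])
        total = 0
        for o in onsets:
            total += ((rec.spike_times_s >= o) &
                      (rec.spike_times_s < o + sched.pip_cycle_s)).sum()
        assert psth.mean_count_per_bin.sum() * psth.n_pips == pytest.approx(total)

    def test_bin_width_wider_than_cycle_rejected(self):
        rec = make_recording([])
        with pytest.raises(ValueError, match="cycle"):
            compute_psth(rec, "pre", bin_width_ms=60.0)

    def test_evoked_window_mass_matches_expectation(self):
        # planted response 8-18 ms at 100 events/s on top of low spontaneous
        cfg = SpikeSimConfig(n_channels=1, spontaneous_rate=1.0,
                             tone_response=ToneResponseSpec(0.008, 0.010, 100.0),
                             seed=9)
        rec = gen_spike_dataset(cfg)[0]
        psth = compute_psth(rec, "pre", bin_width_ms=0.5)
        lo = np.searchsorted(psth.bin_edges_ms, 8.0)
        hi = np.searchsorted(psth.bin_edges_ms, 18.0)
        mass = psth.mean_count_per_bin[lo:hi].sum() * psth.n_pips
        expected = 100.0 * 0.010 * psth.n_pips + 1.0 * 0.010 * psth.n_pips
        se = np.sqrt(expected)
        assert abs(mass - expected) < 3 * se


class TestToneResponseMetrics:
    def _psth_pair(self, onset_s, dur_s, rate, seed=13, post_scale=1.0):
        cfg = SpikeSimConfig(
            n_channels=1, spontaneous_rate=2.0,
            tone_response=ToneResponseSpec(onset_s, dur_s, rate, post_scale),
            seed=seed)
        rec = gen_spike_dataset(cfg)[0]
        spont = compute_bin_rates(rec, "PRE_silence")
        return (compute_psth(rec, "pre", 0.5), compute_psth(rec, "t1", 0.5), spont)

    def test_early_onset_is_invalid(self):
        p_pre, p_t1, spont = self._psth_pair(0.0030, 0.010, 300.0)
        m = tone_response_metrics(p_pre, p_t1, spont)
        assert m.onset_latency_ms is not None and m.onset_latency_ms <= 3.4
        assert not m.valid

    def test_flat_psth_is_unresponsive(self):
        p_pre, p_t1, spont = self._psth_pair(0.008, 0.010, 0.0)
        m = tone_response_metrics(p_pre, p_t1, spont)
        assert not m.responsive and m.onset_latency_ms is None

    def test_planted_onset_and_duration_recovered(self):
        p_pre, p_t1, spont = self._psth_pair(0.008, 0.010, 400.0)
        m = tone_response_metrics(p_pre, p_t1, spont)
        assert m.valid and m.responsive
        assert m.onset_latency_ms == pytest.approx(8.0, abs=0.5)    # 1 bin
        assert m.response_duration_ms == pytest.approx(10.0, abs=1.0)  # 2 bins

    def test_suppressed_t1_gives_negative_delta(self):
        p_pre, p_t1, spont = self._psth_pair(0.008, 0.010, 400.0, post_scale=0.3)
        m = tone_response_metrics(p_pre, p_t1, spont)
        d = delta(m.pre_rate, m.post_rate)
        assert d.classification == "suppressed"


class TestDelta:
    @pytest.mark.parametrize("pre,post,expected,cls", [
        (10, 10, 0.0, "unchanged"),
        (0, 20, 1.0, "potentiated"),
        (30, 10, -0.5, "suppressed"),
    ])
    def test_printed_formula_arithmetic(self, pre, post, expected, cls):
        d = delta(pre, post)
        assert d.delta == pytest.approx(expected)
        assert d.classification == cls

    def test_both_zero_not_computable(self):
        d = delta(0.0, 0.0)
        assert not d.computable and np.isnan(d.delta)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounded_and_antisymmetric(self, a, b):
        if a + b == 0:
            return
        d_ab, d_ba = delta(a, b), delta(b, a)
        assert abs(d_ab.delta) <= 1.0
        assert d_ab.delta == pytest.approx(-d_ba.delta, abs=1e-12)
        if abs(d_ab.delta) == 1.0:
            # |delta| reaches 1 only when one rate is (numerically) zero
            assert min(a, b) <= max(a, b) * 1e-15
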