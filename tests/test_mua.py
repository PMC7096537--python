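"""Multiunit-activity statistics: detection, rhythmicity, waveforms, fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gjprop import mua
from gjprop.errors import (DegenerateWaveError, FeatureUndefinedError,
                           FitFailureError, NoPeakError, UndefinedResultError)
from gjprop.synth import make_waveform_template

FS = 25000.0


def trace_with_events(event_times_s, snr=8.0, dur_s=2.0, seed=0, kind="FS"):
    rng = np.random.default_rng(seed)
    tr = rng.normal(0, 1.0, int(dur_s * FS))
    tmpl = make_waveform_template(kind, FS)
    iv = int(np.argmin(tmpl))
    for t in event_times_s:
        i0 = int(round(t * FS)) - iv
        tr[i0:i0 + tmpl.size] += snr * tmpl
    return tr


class TestDetection:
    def test_no_detections_on_noise_free_flat_trace_with_given_sd(self):
        ev = mua.detect_spikes(np.zeros(25000), FS, sd=1.0)
        assert ev.times_s.size == 0

    def test_flat_trace_without_sd_estimate_raises(self):
        with pytest.raises(ValueError):
            mua.detect_spikes(np.zeros(1000), FS)

    def test_injected_events_detected_with_small_timing_error(self):
        times = np.arange(0.1, 1.9, 0.05)
        tr = trace_with_events(times, snr=8.0)
        ev = mua.detect_spikes(tr, FS, k_sd=4.0)
        assert ev.times_s.size == times.size
        err = np.abs(ev.times_s - times)
        assert np.max(err) < 0.2e-3

    def test_raising_threshold_never_adds_detections(self):
        tr = trace_with_events(np.arange(0.1, 1.9, 0.05), snr=5.0)
        t4 = set(np.round(mua.detect_spikes(tr, FS, k_sd=4.0).times_s, 6))
        t6 = set(np.round(mua.detect_spikes(tr, FS, k_sd=6.0).times_s, 6))
        assert t6 <= t4


class TestRates:
    def test_rate_arithmetic(self):
        assert mua.firing_rate(np.linspace(0, 2.9, 30), 3.0) == pytest.approx(10.0)

    def test_empty_segment_rate_zero(self):
        assert mua.firing_rate(np.empty(0), 3.0) == 0.0

    def test_concatenation_preserves_rate(self):
        seg = np.linspace(0, 2.9, 30)
        both = np.concatenate([seg, seg + 3.0])
        assert mua.firing_rate(both, 6.0) == mua.firing_rate(seg, 3.0)


class TestRhythmicity:
    def test_perfectly_locked_on_phase(self):
        spikes = 0.010 + 0.050 * np.arange(60)    # all at 10 ms phase (ON)
        assert mua.rhythmicity(spikes).value == 1.0

    def test_anti_locked_off_phase(self):
        spikes = 0.040 + 0.050 * np.arange(60)    # all at 40 ms phase (OFF)
        assert mua.rhythmicity(spikes).value == 0.0

    def test_uniform_train_gives_exactly_half(self):
        # one spike every 0.5 ms tiles the 50 ms period evenly
        spikes = np.arange(0, 3.0, 0.0005)
        assert mua.rhythmicity(spikes).value == 0.5

    def test_empty_segment_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            mua.rhythmicity(np.empty(0))

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=30)
    def test_invariant_to_whole_period_shifts(self, k):
        spikes = np.array([0.012, 0.018, 0.031])
        shifted = spikes + k * 0.050
        assert mua.rhythmicity(shifted).value == \
            mua.rhythmicity(spikes).value

    def test_shift_equivariance(self):
        spikes = np.array([0.012, 0.018, 0.031, 0.044])
        a = mua.rhythmicity(spikes, circular_shift_ms=0.0).value
        b = mua.rhythmicity(spikes + 0.003, circular_shift_ms=3.0).value
        assert a == pytest.approx(b)


class TestSegmentation:
    def test_epoch_layout(self):
        rec = mua.MEARecording(traces=np.zeros((16, int(120 * FS) // 10)),
                               fs_hz=FS / 10)
        stim, base = mua.segment_epoch(rec)
        assert len(stim) == 6
        assert len(base) == 4
        for a, b in stim:
            assert b - a == pytest.approx(3.0)
        # stimulation segments are disjoint and baselines never overlap them
        allsegs = sorted(stim + base)
        for (a1, b1), (a2, b2) in zip(allsegs, allsegs[1:]):
            assert b1 <= a2 + 1e-9

    def test_inconsistent_metadata_raises(self):
        rec = mua.MEARecording(traces=np.zeros((16, int(10 * FS) // 10)),
                               fs_hz=FS / 10)
        with pytest.raises(ValueError):
            mua.segment_epoch(rec)


class TestWaveforms:
    def test_template_widths_straddle_the_boundary(self):
        fs_t = make_waveform_template("FS", FS)
        rs_t = make_waveform_template("RS", FS)
        wf = mua.waveform_features(fs_t, FS)
        wr = mua.waveform_features(rs_t, FS)
        assert wf.width_ms < 0.55 < wr.width_ms
        assert wf.width_ms == pytest.approx(0.30, abs=0.08)
        assert wr.width_ms == pytest.approx(0.80, abs=0.12)

    def test_scale_and_translation_invariance(self):
        t = make_waveform_template("FS", FS)
        a = mua.waveform_features(t, FS)
        b = mua.waveform_features(2.0 * t, FS)
        c = mua.waveform_features(np.concatenate([np.zeros(10), t]), FS)
        assert a.width_ms == b.width_ms == c.width_ms
        assert a.amplitude_ratio == pytest.approx(b.amplitude_ratio)

    def test_no_post_valley_peak_is_undefined(self):
        snippet = -np.linspace(0, 1, 50)   # monotone, valley at the end
        with pytest.raises(FeatureUndefinedError):
            mua.waveform_features(snippet, FS)

    @pytest.mark.parametrize("width,expected", [
        (0.30, "fast_spiking"), (0.80, "regular_spiking"),
        (0.55, "fast_spiking"),     # tie at the boundary is strict
    ])
    def test_classification_boundary(self, width, expected):
        f = mua.WaveformFeatures(width_ms=width, amplitude_ratio=2.0)
        assert mua.classify_unit(f) == expected


class TestAllFsProbability:
    def test_ten_cases_near_one_in_a_thousand(self):
        p = mua.all_fs_probability(10, 0.5)
        assert p == pytest.approx(0.0977, abs=0.0001)
        assert p == pytest.approx(0.1, abs=0.005)

    def test_single_case_and_empty_product(self):
        assert mua.all_fs_probability(1, 0.5) == 50.0
        assert mua.all_fs_probability(0, 0.123) == 100.0


class TestPsth:
    def test_point_mass_latency(self):
        spikes = 0.005 + 0.050 * np.arange(100)
        lat = mua.psth_first_peak(spikes)
        assert lat == pytest.approx(5.0, abs=0.5)

    def test_uniform_phases_have_no_peak(self):
        rng = np.random.default_rng(1)
        spikes = rng.uniform(0, 5.0, 500)
        with pytest.raises(NoPeakError):
            mua.psth_first_peak(spikes)

    def test_jittered_locked_unit(self):
        rng = np.random.default_rng(2)
        spikes = 0.050 * np.arange(200) + 0.008 + rng.normal(0, 1e-3, 200)
        lat = mua.psth_first_peak(spikes)
        assert abs(lat - 8.0) <= 1.0

    def test_speed_arithmetic_and_linearity(self):
        assert mua.propagation_speed_mea(2.0, 6.0, 200.0) == pytest.approx(50.0)
        assert mua.propagation_speed_mea(2.0, 6.0, 400.0) == pytest.approx(100.0)
        with pytest.raises(DegenerateWaveError):
            mua.propagation_speed_mea(6.0, 6.0, 200.0)


class TestSigmoidFit:
    def test_step_data_recover_step_location(self):
        k = np.array([4.5, 5.5, 6.5, 7.5, 8.5, 9.5])
        y = (k >= 7.0).astype(float)
        fit = mua.fit_sigmoid_threshold(k, y)
        assert fit.threshold_mm == pytest.approx(7.0, abs=0.5)

    def test_translation_equivariance(self):
        k = np.array([4.5, 6.0, 7.0, 8.0, 9.0, 10.5])
        y = 1 / (1 + np.exp(-(k - 7.6) / 0.8))
        f0 = mua.fit_sigmoid_threshold(k, y)
        f1 = mua.fit_sigmoid_threshold(k + 1.0, y)
        assert f1.threshold_mm - f0.threshold_mm == pytest.approx(1.0, abs=0.05)

    def test_degenerate_data_raise(self):
        k = np.array([4.0, 5.0, 6.0, 7.0])
        with pytest.raises(FitFailureError):
            mua.fit_sigmoid_threshold(k, np.zeros(4))
        with pytest.raises(ValueError):
            mua.fit_sigmoid_threshold(k[:3], np.array([0, 0.5, 1.0]))


class TestMedianDiff:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        d, (lo, hi) = mua.median_diff_ci(a, a, n_boot=2000, seed=0)
        assert d == 0.0
        assert lo <= 0.0 <= hi

    def test_constant_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 40)
        d, (lo, hi) = mua.median_diff_ci(a, a + 2.5, n_boot=2000, seed=0)
        assert d == pytest.approx(2.5)
        assert lo <= 2.5 <= hi

    def test_too_few_bootstrap_draws_rejected(self):
        with pytest.raises(ValueError):
            mua.median_diff_ci(np.ones(3), np.ones(3), n_boot=50)


class TestRankSum:
    def test_identical_samples_give_zero(self):
        a = np.arange(10.0)
        assert mua.ranksum_z(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        assert mua.ranksum_z(a, b) == pytest.approx(-mua.ranksum_z(b, a))

    def test_separated_samples_give_large_z(self):
        z = mua.ranksum_z(np.arange(20.0), np.arange(20.0) + 100)
        assert z < -3
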