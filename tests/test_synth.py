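"""Synthetic MEA generator and end-to-end recovery of its ground truth."""

import numpy as np
import pytest

from gjprop import mua
from gjprop.synth import (SyntheticConfig, generate_recording,
                          generate_threshold_dataset, make_waveform_template)
from gjprop.mua import StimTrain


def stim_segment_spikes(events, rec):
    """Detected spike times inside stimulation segments, re-zeroed to each
    trial onset so phases can be folded on the pulse period."""
    stim, _ = mua.segment_epoch(rec)
    out = []
    for a, b in stim:
        sel = events.times_s[(events.times_s >= a) & (events.times_s < b)]
        out.append(sel - a)
    return np.concatenate(out) if out else np.empty(0)


class TestTemplates:
    def test_fs_is_narrow_rs_is_broad(self):
        fs = make_waveform_template("FS", 25000.0)
        rs = make_waveform_template("RS", 25000.0)
        assert mua.waveform_features(fs, 25000.0).width_ms < 0.55
        assert mua.waveform_features(rs, 25000.0).width_ms > 0.55

    def test_valley_normalised_to_unit_amplitude(self):
        for kind in ("FS", "RS"):
            t = make_waveform_template(kind, 25000.0)
            assert t.min() == pytest.approx(-1.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            make_waveform_template("FS", 5000.0)


class TestGeneration:
    def test_determinism_under_seed(self):
        cfg = SyntheticConfig(stim=StimTrain(n_trials=1), epoch_s=30.0,
                              seed=7)
        a, _ = generate_recording(cfg)
        b, _ = generate_recording(cfg)
        assert np.array_equal(a.traces, b.traces)

    def test_no_locked_spikes_outside_span_without_propagation(
            self, no_propagation_recording):
        rec, gt = no_propagation_recording
        lo, hi = rec.illuminated
        for ch in range(rec.n_channels):
            if not (lo <= ch <= hi):
                assert gt.locked_times_s[ch].size == 0
                assert not gt.locked[ch]

    def test_injected_delay_follows_distance_over_speed(
            self, propagation_recording):
        rec, gt = propagation_recording
        for ch in range(rec.n_channels):
            dist = rec.channel_distance_um(ch)
            if gt.locked[ch] and dist > 0:
                assert gt.delay_ms[ch] == pytest.approx(dist / 60.0)
        # 300 um at 60 mm/s -> 5 ms
        lo, hi = rec.illuminated
        assert gt.delay_ms[hi + 3] == pytest.approx(5.0)

    def test_inconsistent_extent_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(extent_um=5000.0)


class TestEndToEndRecovery:
    def test_rhythmicity_high_on_locked_low_on_baseline_channels(
            self, propagation_recording):
        rec, gt = propagation_recording
        lo, hi = rec.illuminated
        locked_ch, baseline_ch = lo, 0       # channel 0 is 600 um away
        ev_l = mua.detect_spikes(rec.traces[locked_ch], rec.fs_hz)
        r_l = mua.rhythmicity(stim_segment_spikes(ev_l, rec))
        assert r_l.value > 0.9

        ev_b = mua.detect_spikes(rec.traces[baseline_ch], rec.fs_hz)
        # baseline spiking is Poisson: rhythmicity within binomial error
        # of 0.5
        r_b = mua.rhythmicity(stim_segment_spikes(ev_b, rec))
        se = 0.5 / np.sqrt(r_b.n_spikes)
        assert abs(r_b.value - 0.5) < 4 * se

    def test_firing_rate_rises_during_stimulation(self, propagation_recording):
        rec, _ = propagation_recording
        lo, _ = rec.illuminated
        ev = mua.detect_spikes(rec.traces[lo], rec.fs_hz)
        stim, base = mua.segment_epoch(rec)
        r_stim = np.mean([mua.firing_rate(
            ev.times_s[(ev.times_s >= a) & (ev.times_s < b)], b - a)
            for a, b in stim])
        r_base = np.mean([mua.firing_rate(
            ev.times_s[(ev.times_s >= a) & (ev.times_s < b)], b - a)
            for a, b in base])
        assert r_stim > 5 * r_base + 5

    def test_unit_classification_accuracy_at_snr8(self):
        """>= 95% of synthetic units recover their injected class from the
        averaged detected waveform at SNR 8."""
        correct = total = 0
        for seed in range(10):
            cls = {ch: ("RS" if (ch + seed) % 2 else "FS")
                   for ch in range(16)}
            cfg = SyntheticConfig(stim=StimTrain(n_trials=1), epoch_s=30.0,
                                  unit_class_per_channel=cls, snr=8.0,
                                  baseline_rate_hz=4.0, seed=200 + seed)
            rec, gt = generate_recording(cfg)
            for ch in range(rec.n_channels):
                ev = mua.detect_spikes(rec.traces[ch], rec.fs_hz, channel=ch)
                # a stable average needs a reasonable event count
                if ev.snippets.shape[0] < 60:
                    continue
                mean_wf = mua.amplitude_window_filter(ev).snippets.mean(axis=0)
                feats = mua.waveform_features(mean_wf, rec.fs_hz)
                total += 1
                correct += (mua.classify_unit(feats)
                            == {"FS": "fast_spiking",
                                "RS": "regular_spiking"}[gt.unit_class[ch]])
        assert total >= 100
        assert correct / total >= 0.95

    @pytest.mark.parametrize("speed", [20.0, 40.0, 60.0, 80.0, 100.0])
    def test_propagation_speed_recovery_within_one_psth_bin(self, speed):
        cfg = SyntheticConfig(stim=StimTrain(n_trials=1), epoch_s=30.0,
                              speed_mm_s=speed, extent_um=400.0,
                              phase_jitter_ms=0.3, seed=int(speed))
        rec, gt = generate_recording(cfg)
        lo, hi = rec.illuminated
        near, far = hi, hi + 4           # inside edge vs 400 um out
        lat = {}
        for ch in (near, far):
            ev = mua.detect_spikes(rec.traces[ch], rec.fs_hz)
            lat[ch] = mua.psth_first_peak(stim_segment_spikes(ev, rec))
        sep = (far - near) * rec.spacing_um
        dt_est = lat[far] - lat[near]
        dt_true = sep / speed
        assert abs(dt_est - dt_true) <= 1.0      # one 1 ms histogram bin
        v_est = mua.propagation_speed_mea(lat[near], lat[far], sep)
        assert v_est > 0


class TestThresholdDataset:
    def test_cumulative_proportions_non_decreasing(self):
        df = generate_threshold_dataset(np.arange(4.5, 12.0, 1.0), seed=0)
        assert (np.diff(df["cumulative_proportion"]) >= 0).all()

    def test_infinite_slope_limit_is_a_step(self):
        df = generate_threshold_dataset(np.arange(4.5, 12.0, 0.5),
                                        true_threshold_mm=8.0,
                                        slope_per_mm=1e6, n_slices=50, seed=1)
        y = df["cumulative_proportion"].to_numpy()
        assert np.all(y[df["k_mm"] < 8.0] == 0.0)
        assert np.all(y[df["k_mm"] > 8.0] == 1.0)

    def test_threshold_recovery_at_experimental_sample_size(self):
        """n = 24 slices: fitted 50% point within 0.5 mM of the injected
        8.0 mM threshold (median over replicate datasets)."""
        errs = []
        for seed in range(12):
            df = generate_threshold_dataset(
                np.arange(4.5, 12.5, 0.5), true_threshold_mm=8.0,
                slope_per_mm=1.5, n_slices=24, seed=seed)
            fit = mua.fit_sigmoid_threshold(df["k_mm"],
                                            df["cumulative_proportion"])
            errs.append(abs(fit.threshold_mm - 8.0))
        assert np.median(errs) < 0.5

    def test_consistency_at_large_n(self):
        df = generate_threshold_dataset(np.arange(4.0, 13.0, 0.25),
                                        true_threshold_mm=8.0,
                                        slope_per_mm=1.5, n_slices=20000,
                                        seed=3)
        fit = mua.fit_sigmoid_threshold(df["k_mm"],
                                        df["cumulative_proportion"])
        assert fit.threshold_mm == pytest.approx(8.0, abs=0.1)
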