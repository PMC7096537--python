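"""The MUA analysis pipeline on a synthetic propagation recording.

Generates a 16-channel recording with a 59.1 mm/s propagating response
(the experimental median speed used as generator ground truth), runs spike
detection, firing rates, rhythmicity, waveform classification and the
PSTH first-peak speed estimate, and writes per-channel results.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gjprop import mua
from gjprop.mua import StimTrain
from gjprop.synth import SyntheticConfig, generate_recording

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    cfg = SyntheticConfig(stim=StimTrain(n_trials=2), epoch_s=52.0,
                          speed_mm_s=59.1, extent_um=400.0, k_out_mm=9.5,
                          phase_jitter_ms=0.3, seed=42)
    rec, gt = generate_recording(cfg)
    stim_segs, base_segs = mua.segment_epoch(rec)

    rows = []
    latencies = {}
    for ch in range(rec.n_channels):
        ev = mua.detect_spikes(rec.traces[ch], rec.fs_hz, channel=ch)
        dist = rec.channel_distance_um(ch)
        phases = np.concatenate([
            ev.times_s[(ev.times_s >= a) & (ev.times_s < b)] - a
            for a, b in stim_segs]) if ev.times_s.size else np.empty(0)
        shift = mua.DISTAL_SHIFT_MS if dist >= 150 else 0.0
        row = dict(channel=ch, distance_um=dist,
                   locked_truth=bool(gt.locked[ch]),
                   n_detected=ev.times_s.size)
        row["stim_rate_hz"] = float(np.mean([mua.firing_rate(
            ev.times_s[(ev.times_s >= a) & (ev.times_s < b)], b - a)
            for a, b in stim_segs]))
        row["base_rate_hz"] = float(np.mean([mua.firing_rate(
            ev.times_s[(ev.times_s >= a) & (ev.times_s < b)], b - a)
            for a, b in base_segs]))
        try:
            row["rhythmicity"] = round(mua.rhythmicity(
                phases, circular_shift_ms=shift).value, 3)
        except Exception:
            row["rhythmicity"] = np.nan
        try:
            latencies[ch] = mua.psth_first_peak(phases)
            row["first_peak_ms"] = round(latencies[ch], 2)
        except Exception:
            row["first_peak_ms"] = np.nan
        if ev.snippets.shape[0] >= 60:
            wf = mua.amplitude_window_filter(ev).snippets.mean(axis=0)
            try:
                feats = mua.waveform_features(wf, rec.fs_hz)
                row["width_ms"] = round(feats.width_ms, 3)
                row["class"] = mua.classify_unit(feats)
            except Exception:
                pass
        rows.append(row)

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "mua_channels.csv", index=False)
    print(df.to_string(index=False))

    lo, hi = rec.illuminated
    near, far = hi, hi + 4
    if near in latencies and far in latencies:
        v = mua.propagation_speed_mea(latencies[near], latencies[far],
                                      (far - near) * rec.spacing_um)
        print(f"\nPSTH first-peak speed estimate: {v:.1f} mm/s "
              f"(injected {cfg.speed_mm_s} mm/s)")
    print(f"all-FS binomial probability for n=10 at p=0.5: "
          f"{mua.all_fs_probability(10):.4f}%")


if __name__ == "__main__":
    main()
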