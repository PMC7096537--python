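"""Synthetic 16-channel MEA recordings with complete ground truth.

Emulates the statistical structure of the optogenetic propagation
experiments: channels within the illuminated span carry spikes tightly
locked to the 20 Hz / 50% duty light pulses (four per pulse by default);
channels beyond the span carry locked spikes only when propagation is
enabled and they lie within the propagation extent, delayed by
distance / speed; every channel additionally carries Poisson background
spiking whose rate grows linearly with [K+]o above baseline.  Spikes are
pasted as fast- or regular-spiking waveform templates over white Gaussian
noise (an ideal 300 Hz high-pass is assumed).  The generator also produces
the propagation-vs-[K+]o datasets used to validate the sigmoid threshold
fit.

The generator is deliberately independent of the biophysical network
simulator: it provides ground truth for the analysis pipeline, not a
forward model of extracellular fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mua import MEARecording, StimTrain

__all__ = [
    "SyntheticConfig", "GroundTruth", "make_waveform_template",
    "generate_recording", "generate_threshold_dataset",
]

BASELINE_K_MM = 3.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete specification of one synthetic recording."""

    n_channels: int = 16
    fs_hz: float = 25000.0
    spacing_um: float = 100.0
    illuminated: tuple[int, int] = (6, 9)

    unit_class: str = "FS"                   # waveform class on all channels
    unit_class_per_channel: dict | None = None
    locked_phase_ms: float = 4.0             # first locked spike phase in a pulse
    intra_burst_isi_ms: float = 2.5
    phase_jitter_ms: float = 0.5
    illum_spikes_per_pulse: int = 4
    distal_spikes_per_pulse: int = 1
    baseline_rate_hz: float = 1.0
    rate_per_mm_k: float = 1.0               # extra Hz per mM [K+]o above 3.5

    propagation: bool = True
    speed_mm_s: float = 60.0
    extent_um: float = 400.0                 # beyond the illumination edge

    noise_sd: float = 1.0
    snr: float = 8.0                         # template valley amplitude / noise SD
    amp_jitter: float = 0.05

    stim: StimTrain = field(default_factory=StimTrain)
    epoch_s: float = 120.0
    k_out_mm: float = 3.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.illuminated
        if not (0 <= lo <= hi < self.n_channels):
            raise ValueError("illuminated span outside the channel range")
        if self.propagation and self.speed_mm_s <= 0:
            raise ValueError("speed must be positive when propagation is enabled")
        if self.phase_jitter_ms < 0:
            raise ValueError("jitter must be non-negative")
        max_dist = self.spacing_um * max(
            self.illuminated[0], self.n_channels - 1 - self.illuminated[1])
        if self.propagation and self.extent_um > max_dist + self.spacing_um * 16:
            raise ValueError("propagation extent far beyond the array")


@dataclass
class GroundTruth:
    """Everything needed to score the analysis pipeline without re-inference."""

    config: SyntheticConfig
    unit_class: list[str]                    # per channel
    delay_ms: np.ndarray                     # injected locked-phase delay per channel
    locked: np.ndarray                       # bool per channel
    locked_times_s: list[np.ndarray]
    baseline_times_s: list[np.ndarray]


def make_waveform_template(kind: str, fs_hz: float,
                           window_ms: float = 3.0) -> np.ndarray:
    """Biphasic extracellular spike template, valley normalised to -1.

    FS: narrow (valley-to-peak < 0.55 ms) with a prominent overshoot;
    RS: broad (> 0.55 ms) with a smaller overshoot.
    """
    if fs_hz < 10000:
        raise ValueError("template needs fs >= 10 kHz")
    if kind == "FS":
        t_peak, sig_v, sig_p, peak_amp = 0.30, 0.10, 0.16, 0.55
    elif kind == "RS":
        t_peak, sig_v, sig_p, peak_amp = 0.80, 0.22, 0.40, 0.30
    else:
        raise ValueError("kind must be 'FS' or 'RS'")
    t = np.arange(int(round(window_ms * 1e-3 * fs_hz))) / fs_hz * 1e3
    t_valley = 1.0
    w = (-np.exp(-0.5 * ((t - t_valley) / sig_v) ** 2)
         + peak_amp * np.exp(-0.5 * ((t - t_valley - t_peak) / sig_p) ** 2))
    return w / abs(w.min())


def _locked_spike_times(cfg: SyntheticConfig, rng: np.random.Generator,
                        delay_ms: float, n_per_pulse: int) -> np.ndarray:
    """Pulse-locked spike times over all trials, seconds."""
    st = cfg.stim
    times = []
    n_pulses = int(round(st.stim_s * st.pulse_hz))
    for onset in st.trial_onsets_s():
        for p in range(n_pulses):
            t0_ms = onset * 1e3 + p * st.period_ms + delay_ms
            for j in range(n_per_pulse):
                ph = (cfg.locked_phase_ms + j * cfg.intra_burst_isi_ms
                      + rng.normal(0.0, cfg.phase_jitter_ms))
                ph = min(max(ph, 0.5), st.on_ms - 0.5)
                times.append((t0_ms + ph) * 1e-3)
    return np.sort(np.array(times))


def generate_recording(cfg: SyntheticConfig) -> tuple[MEARecording, GroundTruth]:
    """Render a synthetic recording and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(cfg.epoch_s * cfg.fs_hz))
    traces = rng.normal(0.0, cfg.noise_sd,
                        size=(cfg.n_channels, n_samp)).astype(np.float32)

    rate = cfg.baseline_rate_hz + cfg.rate_per_mm_k * max(
        0.0, cfg.k_out_mm - BASELINE_K_MM)
    templates = {k: make_waveform_template(k, cfg.fs_hz) for k in ("FS", "RS")}
    classes = []
    delays = np.zeros(cfg.n_channels)
    locked_flags = np.zeros(cfg.n_channels, dtype=bool)
    locked_all, base_all = [], []

    rec = MEARecording(traces=traces, fs_hz=cfg.fs_hz, spacing_um=cfg.spacing_um,
                       illuminated=cfg.illuminated, stim=cfg.stim,
                       k_out_mm=cfg.k_out_mm)
    for ch in range(cfg.n_channels):
        cls = (cfg.unit_class_per_channel or {}).get(ch, cfg.unit_class)
        classes.append(cls)
        dist = rec.channel_distance_um(ch)
        inside = dist == 0.0
        if inside:
            locked_flags[ch] = True
            delays[ch] = 0.0
            locked = _locked_spike_times(cfg, rng, 0.0, cfg.illum_spikes_per_pulse)
        elif cfg.propagation and dist <= cfg.extent_um:
            locked_flags[ch] = True
            delays[ch] = dist / cfg.speed_mm_s      # um / (um/ms) = ms
            locked = _locked_spike_times(cfg, rng, delays[ch],
                                         cfg.distal_spikes_per_pulse)
        else:
            locked = np.empty(0)
        n_base = rng.poisson(rate * cfg.epoch_s)
        baseline = np.sort(rng.uniform(0.0, cfg.epoch_s, size=n_base))
        locked_all.append(locked)
        base_all.append(baseline)

        tmpl = templates[cls]
        i_valley = int(np.argmin(tmpl))
        amp = cfg.snr * cfg.noise_sd
        for t in np.concatenate([locked, baseline]):
            i0 = int(round(t * cfg.fs_hz)) - i_valley
            if i0 < 0 or i0 + tmpl.size > n_samp:
                continue
            a = amp * (1.0 + rng.normal(0.0, cfg.amp_jitter))
            traces[ch, i0:i0 + tmpl.size] += (a * tmpl).astype(np.float32)

    gt = GroundTruth(config=cfg, unit_class=classes, delay_ms=delays,
                     locked=locked_flags, locked_times_s=locked_all,
                     baseline_times_s=base_all)
    return rec, gt


def generate_threshold_dataset(k_levels_mm: np.ndarray,
                               true_threshold_mm: float = 8.0,
                               slope_per_mm: float = 1.5,
                               n_slices: int = 24,
                               seed: int | None = None) -> pd.DataFrame:
    """Per-level cumulative propagation proportions from a logistic model.

    Each synthetic slice first propagates at a [K+]o drawn from the
    logistic distribution with location ``true_threshold_mm`` and scale
    ``1 / slope_per_mm``; the returned cumulative proportion at each
    tested level is the fraction of slices whose threshold is at or below
    it (non-decreasing by construction).
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    k = np.sort(np.asarray(k_levels_mm, dtype=float))
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n_slices)
    slice_thresholds = true_threshold_mm + np.log(u / (1 - u)) / slope_per_mm
    prop = np.array([(slice_thresholds <= lev).mean() for lev in k])
    return pd.DataFrame({"k_mm": k, "cumulative_proportion": prop})
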