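"""Multiunit-activity (MUA) analysis of multichannel extracellular recordings.

Implements the statistics used to characterise optogenetically evoked,
gap-junction-mediated propagation on a 16-channel linear probe (25 kHz,
100 um spacing): amplitude-threshold spike detection at 4 SDs, per-segment
firing rates, the ON-phase rhythmicity index of the 20 Hz / 50% duty
photostimulation train, valley-to-peak waveform features with the 0.55 ms
fast-spiking / regular-spiking boundary, peristimulus-histogram first-peak
latencies and the derived propagation speed, the sigmoidal fit of
propagation probability against [K+]o, and the nonparametric summary
statistics (tie-corrected rank-sum z, bootstrap median-difference CI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (DegenerateWaveError, FeatureUndefinedError,
                     FitFailureError, NoPeakError, UndefinedResultError)

__all__ = [
    "StimTrain", "MEARecording", "SpikeEvents", "WaveformFeatures",
    "RhythmicityResult", "SigmoidFit", "detect_spikes", "firing_rate",
    "rhythmicity", "segment_epoch", "waveform_features", "classify_unit",
    "all_fs_probability", "psth_phase_histogram", "psth_first_peak",
    "propagation_speed_mea", "fit_sigmoid_threshold", "median_diff_ci",
    "ranksum_z",
]

FS_RS_WIDTH_BOUNDARY_MS = 0.55
DEFAULT_PERIOD_MS = 50.0
DEFAULT_ON_FRACTION = 0.5
#: circular shift applied to segments recorded >= 150 um from the
#: illumination edge, compensating the expected propagation delay
DISTAL_SHIFT_MS = 3.0


@dataclass(frozen=True)
class StimTrain:
    """Photostimulation protocol metadata."""

    cycle_s: float = 20.0
    stim_s: float = 3.0
    pulse_hz: float = 20.0
    duty: float = 0.5
    n_trials: int = 6
    first_onset_s: float = 6.0

    @property
    def period_ms(self) -> float:
        return 1e3 / self.pulse_hz

    @property
    def on_ms(self) -> float:
        return self.duty * self.period_ms

    def trial_onsets_s(self) -> np.ndarray:
        return self.first_onset_s + np.arange(self.n_trials) * self.cycle_s


@dataclass
class MEARecording:
    """Multichannel high-pass-filtered extracellular recording."""

    traces: np.ndarray            # (n_channels, n_samples)
    fs_hz: float = 25000.0
    spacing_um: float = 100.0
    illuminated: tuple[int, int] = (6, 9)   # inclusive 0-based channel span
    stim: StimTrain = field(default_factory=StimTrain)
    k_out_mm: float = 3.5
    condition: str = "baseline"

    def __post_init__(self):
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be (n_channels, n_samples)")
        lo, hi = self.illuminated
        if not (0 <= lo <= hi < self.traces.shape[0]):
            raise ValueError("illuminated span outside the channel range")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.fs_hz

    def channel_distance_um(self, channel: int) -> float:
        """Distance from the illumination edge (0 inside the span)."""
        lo, hi = self.illuminated
        if lo <= channel <= hi:
            return 0.0
        return self.spacing_um * (lo - channel if channel < lo else channel - hi)


@dataclass
class SpikeEvents:
    """Detections on one channel: times and aligned waveform snippets."""

    times_s: np.ndarray
    snippets: np.ndarray          # (n_events, n_window)
    channel: int = 0
    fs_hz: float = 25000.0
    threshold: float = 0.0


@dataclass(frozen=True)
class WaveformFeatures:
    width_ms: float               # valley-to-peak
    amplitude_ratio: float        # |valley| / |peak|

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class RhythmicityResult:
    value: float                  # in [0, 1]
    n_spikes: int
    segment_kind: str = "stimulation"


@dataclass(frozen=True)
class SigmoidFit:
    threshold_mm: float           # [K+]o at the 50% point
    slope_per_mm: float
    k_levels: np.ndarray
    proportions: np.ndarray
    fitted: np.ndarray
    residual_ss: float


# ---------------------------------------------------------------------------
# spike detection and basic statistics
# ---------------------------------------------------------------------------

def detect_spikes(trace: np.ndarray, fs_hz: float, k_sd: float = 4.0,
                  refractory_ms: float = 1.0,
                  snippet_ms: tuple[float, float] = (1.0, 2.0),
                  sd: float | None = None, channel: int = 0) -> SpikeEvents:
    """Negative-threshold spike detection at ``k_sd`` standard deviations.

    Detections are negative-going crossings of ``-k_sd * SD`` with a
    refractory lockout; each detection is re-aligned to the local minimum
    within the lockout window before the snippet is cut.  The SD is
    estimated on the analysed trace itself unless given explicitly.
    """
    trace = np.asarray(trace, dtype=float)
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if sd is None:
        sd = float(np.std(trace))
    if sd == 0:
        raise ValueError("flat trace: cannot estimate a detection threshold")
    thr = -k_sd * sd

    below = trace < thr
    crossings = np.nonzero(below[1:] & ~below[:-1])[0] + 1
    lock = int(round(refractory_ms * 1e-3 * fs_hz))
    n_pre = int(round(snippet_ms[0] * 1e-3 * fs_hz))
    n_post = int(round(snippet_ms[1] * 1e-3 * fs_hz))

    times = []
    snips = []
    last = -10 * lock
    for c in crossings:
        if c - last < lock:
            continue
        seg_end = min(c + lock, trace.size)
        c_al = c + int(np.argmin(trace[c:seg_end]))
        last = c_al
        if c_al - n_pre < 0 or c_al + n_post > trace.size:
            continue
        times.append(c_al / fs_hz)
        snips.append(trace[c_al - n_pre:c_al + n_post])
    snips = np.array(snips) if snips else np.empty((0, n_pre + n_post))
    return SpikeEvents(times_s=np.array(times), snippets=snips,
                       channel=channel, fs_hz=fs_hz, threshold=thr)


def firing_rate(spike_times_s: np.ndarray, window_s: float) -> float:
    """Mean firing rate (spikes/s) of a segment of the given duration."""
    if window_s <= 0:
        raise ValueError("window must be positive")
    return len(spike_times_s) / window_s


def rhythmicity(spike_times_s: np.ndarray,
                period_ms: float = DEFAULT_PERIOD_MS,
                on_fraction: float = DEFAULT_ON_FRACTION,
                circular_shift_ms: float = 0.0,
                segment_kind: str = "stimulation") -> RhythmicityResult:
    """ON-phase rhythmicity index of a spike train.

    Spike times are circularly shifted backwards by ``circular_shift_ms``
    (compensating propagation delay on distal channels), folded modulo the
    stimulation period, and the fraction landing in the ON phase
    ``[0, on_fraction * period)`` is returned.  1 = perfectly locked,
    0.5 = unlocked, 0 = anti-locked.
    """
    st = np.asarray(spike_times_s, dtype=float)
    if period_ms <= 0:
        raise ValueError("period must be positive")
    if st.size == 0:
        raise UndefinedResultError("rhythmicity is undefined on an empty segment")
    phases = np.mod(st * 1e3 - circular_shift_ms, period_ms)
    value = float(np.mean(phases < on_fraction * period_ms))
    return RhythmicityResult(value=value, n_spikes=st.size,
                             segment_kind=segment_kind)


def segment_epoch(recording: MEARecording
                  ) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Stimulation and baseline segments (seconds) of one epoch.

    Returns the ``n_trials`` 3 s stimulation segments plus four 3 s
    baseline segments: two immediately before the first trial and two
    immediately after the last (per-condition bookkeeping).
    """
    st = recording.stim
    onsets = st.trial_onsets_s()
    stim_segments = [(float(t0), float(t0 + st.stim_s)) for t0 in onsets]
    last_end = onsets[-1] + st.stim_s
    baseline = [(onsets[0] - 2 * st.stim_s, onsets[0] - st.stim_s),
                (onsets[0] - st.stim_s, onsets[0]),
                (last_end, last_end + st.stim_s),
                (last_end + st.stim_s, last_end + 2 * st.stim_s)]
    end = recording.duration_s
    if baseline[0][0] < 0 or baseline[-1][1] > end or stim_segments[-1][1] > end:
        raise ValueError("stimulation metadata inconsistent with trace length")
    return stim_segments, [(float(a), float(b)) for a, b in baseline]


# ---------------------------------------------------------------------------
# waveform classification
# ---------------------------------------------------------------------------

def waveform_features(snippet: np.ndarray, fs_hz: float) -> WaveformFeatures:
    """Valley-to-peak width (ms) and valley/peak amplitude ratio."""
    snippet = np.asarray(snippet, dtype=float)
    if snippet.size < 3:
        raise FeatureUndefinedError("snippet too short")
    i_valley = int(np.argmin(snippet))
    if i_valley >= snippet.size - 1:
        raise FeatureUndefinedError("no samples after the valley")
    post = snippet[i_valley + 1:]
    i_peak = i_valley + 1 + int(np.argmax(post))
    if snippet[i_peak] <= 0:
        raise FeatureUndefinedError("no positive peak after the valley")
    width_ms = (i_peak - i_valley) / fs_hz * 1e3
    ratio = abs(snippet[i_valley]) / abs(snippet[i_peak])
    return WaveformFeatures(width_ms=width_ms, amplitude_ratio=ratio)


def classify_unit(features: WaveformFeatures) -> str:
    """"regular_spiking" iff width > 0.55 ms (strict), else "fast_spiking"."""
    return ("regular_spiking"
            if features.width_ms > FS_RS_WIDTH_BOUNDARY_MS else "fast_spiking")


def all_fs_probability(n_cases: int, p_fs: float = 0.5) -> float:
    """Probability (%) that all n independent cases are fast-spiking."""
    if n_cases < 0:
        raise ValueError("n_cases must be non-negative")
    if not (0 <= p_fs <= 1):
        raise ValueError("p_fs must be in [0, 1]")
    return 100.0 * p_fs ** n_cases


def amplitude_window_filter(events: SpikeEvents,
                            rel_band: float = 0.35) -> SpikeEvents:
    """Amplitude-based sorting step: keep detections whose (negative) peak
    amplitude lies within ``rel_band`` of the modal event amplitude."""
    if events.times_s.size == 0:
        return events
    amps = -events.snippets.min(axis=1)
    hist, edges = np.histogram(amps, bins=max(10, amps.size // 10))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    keep = np.abs(amps - mode) <= rel_band * mode
    return SpikeEvents(times_s=events.times_s[keep],
                       snippets=events.snippets[keep],
                       channel=events.channel, fs_hz=events.fs_hz,
                       threshold=events.threshold)


# ---------------------------------------------------------------------------
# peristimulus histograms and propagation speed
# ---------------------------------------------------------------------------

def psth_phase_histogram(spike_times_s: np.ndarray,
                         period_ms: float = DEFAULT_PERIOD_MS,
                         bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of spike phases folded on the stimulation period."""
    st = np.asarray(spike_times_s, dtype=float)
    phases = np.mod(st * 1e3, period_ms)
    edges = np.arange(0.0, period_ms + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(phases, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def psth_first_peak(spike_times_s: np.ndarray,
                    period_ms: float = DEFAULT_PERIOD_MS,
                    bin_ms: float = 1.0,
                    min_spikes: int = 10,
                    peak_factor: float = 2.0) -> float:
    """Latency (ms) of the first qualifying peak of the phase histogram.

    The first peak is the earliest local maximum whose count is at least
    ``peak_factor`` times the mean bin count; a flat histogram yields
    :class:`NoPeakError`.
    """
    st = np.asarray(spike_times_s, dtype=float)
    if st.size < min_spikes:
        raise NoPeakError(f"need >= {min_spikes} spikes for a stable histogram")
    counts, centers = psth_phase_histogram(st, period_ms, bin_ms)
    criterion = peak_factor * counts.mean()
    for i in range(len(counts)):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < len(counts) - 1 else -1
        if counts[i] >= criterion and counts[i] >= left and counts[i] >= right:
            return float(centers[i])
    raise NoPeakError("no local maximum exceeds the baseline criterion")


def propagation_speed_mea(latency_near_ms: float, latency_far_ms: float,
                          electrode_separation_um: float) -> float:
    """Propagation speed (mm/s) from two first-peak latencies."""
    dt = latency_far_ms - latency_near_ms
    if dt <= 0:
        raise DegenerateWaveError("far latency must exceed near latency")
    return electrode_separation_um / dt    # um/ms == mm/s


# ---------------------------------------------------------------------------
# threshold fit and nonparametric statistics
# ---------------------------------------------------------------------------

def fit_sigmoid_threshold(k_levels_mm: np.ndarray,
                          cumulative_proportion: np.ndarray) -> SigmoidFit:
    """Least-squares logistic fit of propagation probability vs [K+]o.

    The sigmoid is the 2-parameter logistic with asymptotes 0 and 1 (the
    data are cumulative proportions); the threshold is its 50% abscissa.
    """
    k = np.asarray(k_levels_mm, dtype=float)
    y = np.asarray(cumulative_proportion, dtype=float)
    if np.unique(k).size < 4:
        raise ValueError("need at least 4 distinct [K+]o levels")
    if np.all(y <= 0) or np.all(y >= 1):
        raise FitFailureError("degenerate proportions: all 0 or all 1")

    def logistic(x, x0, s):
        return 1.0 / (1.0 + np.exp(-(x - x0) / s))

    above = k[y >= 0.5]
    x0_init = float(above.min()) if above.size else float(k.max())
    try:
        popt, _ = optimize.curve_fit(
            logistic, k, y, p0=(x0_init, 1.0),
            bounds=((k.min(), 1e-3), (k.max(), 50.0)), maxfev=10000)
    except RuntimeError as e:      # pragma: no cover - scipy failure path
        raise FitFailureError(str(e)) from e
    fitted = logistic(k, *popt)
    return SigmoidFit(threshold_mm=float(popt[0]),
                      slope_per_mm=float(1.0 / popt[1]),
                      k_levels=k, proportions=y, fitted=fitted,
                      residual_ss=float(np.sum((y - fitted) ** 2)))


def median_diff_ci(sample_a: np.ndarray, sample_b: np.ndarray,
                   n_boot: int = 5000, seed: int | None = None,
                   alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Bootstrap percentile CI of median(b) - median(a)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = np.median(b[ib], axis=1) - np.median(a[ia], axis=1)
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return float(np.median(b) - np.median(a)), (float(lo), float(hi))


def ranksum_z(sample_a: np.ndarray, sample_b: np.ndarray,
              return_pvalue: bool = False):
    """Wilcoxon rank-sum z-statistic with tie correction.

    The z is for sample_a's rank sum relative to its null expectation, so
    swapping the samples negates it.  Two-sided normal-approximation
    p-value optionally returned.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, t_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = np.sum(t_counts**3 - t_counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        z = 0.0
    else:
        # continuity-corrected normal approximation
        z = (r1 - mu - 0.5 * np.sign(r1 - mu)) / np.sqrt(var)
    if return_pvalue:
        p = 2.0 * stats.norm.sf(abs(z))
        return float(z), float(min(p, 1.0))
    return float(z)
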