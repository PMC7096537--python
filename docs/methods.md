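# Methods

`gjprop` has two deliberately independent halves: a biophysical simulation
of activity propagating through a gap-junction-coupled network of
fast-spiking (parvalbumin-positive, PV) cortical interneurons, and the
multielectrode multiunit-activity (MUA) statistics used to characterise
such propagation experimentally, exercised on a synthetic-recording
generator with complete ground truth.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
tests do and do not establish.

## The cell model

Each interneuron has three compartments: a soma (27 um long, 29 um
diameter, one segment) and two identical dendrites (200 x 0.8 um, ten
segments each), giving a 21-segment unbranched cable.  Passive properties:
C_m = 1.2 uF/cm2, R_a = 150 Ohm cm, R_m = 10 kOhm cm2.  Maximal
conductances (S/cm2):

| mechanism                 | soma     | dendrite |
|---------------------------|----------|----------|
| transient Na+             | 0.045    | 0.06     |
| delayed-rectifier K+      | 0.018    | 0.009    |
| A-type K+                 | 0.048    | 0.48     |
| slow (D-type) K+          | 7.25e-5  | —        |
| N-type Ca2+               | 3e-4     | —        |
| H-current                 | 1e-5     | —        |
| Ca2+-gated fAHP K+        | 1e-4     | —        |
| Ca2+ shell                | yes      | —        |

### Channel kinetics: a documented stand-in

The conductance table above fixes *how much* of each channel is present,
but not the rate equations.  The package uses a documented fast-spiking
kinetics set, exposed entirely through `KineticsParams` so an alternative
set can be substituted without touching the integrator:

* **Na+ (m3h)** and **delayed-rectifier K+ (n4)** follow the classic
  fast-spiking interneuron formulation of Wang & Buzsaki (1996), with the
  temperature-like factor phi = 5 on h and n and the m gate treated as
  instantaneous (m = m_inf(V)); both rate curves carry voltage offsets
  (defaults +6 mV on m, +4 mV on h — see *Calibration*).
* **A-type K+ (a3b)**: Boltzmann activation (half −20 mV, slope 12 mV,
  tau 2 ms) and inactivation (half −70 mV, slope 7 mV, tau 20 ms).  The
  cubic activation keeps the very large dendritic conductance
  (0.48 S/cm2) essentially closed at rest — with first-order activation
  the dendrites would be pinned to E_K — while still opposing spike
  propagation during the upstroke.
* **slow/D-type K+ (d)**: half −43 mV, slope 8 mV, tau 80 ms.  "Slow K+"
  and "D-type K+" are treated as the same mechanism.
* **N-type Ca2+ (c2)**: half −20 mV, slope 7 mV, tau 2 ms; ohmic with
  E_Ca = +120 mV, feeding a 0.1 um Ca2+ shell (clearance tau 20 ms,
  resting 50 nM).
* **H-current (r)**: half −80 mV, slope 8 mV, tau 150 ms, E_H = −30 mV.
* **fAHP**: instantaneous Ca2+ gating o = Ca2/(Ca2 + Kd2), Kd = 1 uM.

### Condition mapping

* **control** — defaults; [K+]o = 3.5 mM, so E_K = (RT/F) ln(3.5/140) =
  −97.6 mV at 34 C (K_in = 140 mM and T = 307.15 K are configurable
  defaults; 34 C is the midpoint of the 33–36 C bath range).
* **high K+** — [K+]o = 10.5 mM: E_K shifts by (RT/F) ln 3 = +29.1 mV, and
  the leak reversal moves with it in proportion to the K+ fraction of the
  leak (below).
* **4-AP** — R_m multiplied by 5 and every voltage-gated or Ca2+-gated K+
  conductance (delayed rectifier, A-type, D-type, fAHP) scaled to 2% of
  default.  E_K is unchanged.

A pure non-K+ leak would make the resting potential insensitive to
[K+]o, so the leak is modelled as a K+/non-K+ mixture:
E_leak = f·E_K + (1−f)·E_other.  The default K+ fraction is f = 0.80 with
E_other = +41.5 mV (a mixed-cation reversal), fixed so the control leak
reversal is −69.8 mV and the control resting potential sits at −70 mV.
Under these defaults the resting potentials are ≈ −70 mV (control),
≈ −55 mV (high K+) and ≈ −68 mV (4-AP, with five-fold higher input
resistance); all three are quiescent without input, and rheobase for a
25 ms somatic pulse is lower in high K+ than in control.

### Integration

The cable equation is discretised per segment and advanced with a
linearly implicit trapezoid (Crank–Nicolson) step: gating variables are
updated by exact exponential (Rush–Larsen) relaxation from tabulated
steady states and time constants (voltage grid −130..70 mV, 0.05 mV
spacing, linear interpolation), valid at the step midpoint per the
staggered convention; the voltage step then solves a tridiagonal system
per cell (Thomas algorithm) with conductances frozen at the new gate
values.  Because the instantaneous m gate would otherwise lag half a
step, a predictor–corrector pass re-evaluates m at the midpoint of the
predictor solution whenever the cell's voltage moved more than 0.5 mV in
the step (i.e. during spikes).  Default dt = 0.025 ms; halving dt moves
spike times by < 0.05 ms on the standard stimulus.  Somatic spikes are
upward crossings of 0 mV with a 1 ms lockout, timed by linear
interpolation of the crossing.  Non-finite or out-of-range voltages abort
the run with the failing cell and time step.

## The network model

Seventy identical cells are scattered i.i.d.-uniformly in a
650 x 150 x 150 um virtual slice (≈ 4.8e3 cells/mm3); ids are x-ranks.
Each unordered pair is connected independently with probability
p0·(1 − d/400 um) (3-D Euclidean somatic distance d; 400 um is the summed
reach of the two facing dendrites), with at most one 0.3 nS gap junction
per pair.  A junction sits at the same dendritic position p on the left
cell's right dendrite and the right cell's left dendrite, drawn uniformly
from [d/2, 200 um] (the closest geometrically possible point to the tip);
it attaches to the segment containing p (segment-centre convention).
Junctions are ohmic and non-rectifying, I = g·(V_partner − V_self),
evaluated semi-implicitly (own voltage implicit, partner voltage at the
previous step) — adequate because the junction time constant (~2 ms)
is far above dt, and verified by the dt-halving test.

Cells with soma x ≤ 200 um receive a 0.55 nA, 25 ms somatic pulse
starting at t = 50 ms.  Simulations run 150 ms by default: across both
propagating conditions every recruited cell fires its first spike well
before 130 ms, and participation is unchanged at 300 ms.

## Propagation statistics

* **reached id / long propagation** — largest cell id with a spike at or
  after stimulus onset; a *long* propagation reaches id 60 or beyond.
* **speed** — (x_lastRecruited − x_lastStim) / (t_first(lastRecruited) −
  t_first(lastStim)) in mm/s, using each cell's first post-onset spike;
  the references are the largest-x stimulated cell that fired and the
  largest-x recruited cell (ties in x broken by id).
* **participation** — percentage of non-stimulated cells with at least
  one post-onset spike.  Stimulated cells fire by construction, so they
  are excluded from the denominator; this makes 100% attainable.
* **condition experiment** — fresh random networks are simulated until
  the first 200 long propagations are collected (short propagations are
  logged but excluded from the headline medians); conditions are compared
  with the two-sided tie-corrected rank-sum z.

## Calibration of the stand-in model

With the channel kinetics open, four parameters were calibrated once
against the regime the network is required to reproduce — control
activity strictly confined to the stimulated zone; fast, sparse,
failure-prone propagation in high K+; slower, complete, reliable
propagation in 4-AP, with median speeds near 57 and 34 mm/s — and then
frozen: the Na activation and inactivation offsets (+6 / +4 mV), the
leak K+ fraction (0.80), and the connection probability at contact
p0 = 0.48 (only the linear decay of connectivity to 400 um is fixed by
the protocol; its intercept is not).  Mechanistically, the Na offsets
set the spike threshold
high enough that 4-AP recruitment is integration-limited (its speed then
scales with the junction count, hence with p0), while the leak fraction
sets how close high-K+ cells sit to threshold and therefore how fast and
how completely the sparse high-K+ wave spreads.

Two trade-offs of this stand-in are documented rather than hidden: the
high-K+ median participation runs a few points below the 71% calibration
target (the spike-transmission regime that yields ~57 mm/s skips more
cells),
and the high-K+ long-propagation rate is modest (roughly a quarter of
runs), so the condition experiment simulates several networks per long
propagation collected.  Sensitivity: ±0.02 in p0 moves the 4-AP median
speed by roughly ±2 mm/s; ±0.01 in the leak fraction moves the high-K+
long-propagation rate strongly.

## The MUA pipeline

Spike detection takes negative-going crossings of −4·SD (SD estimated on
the analysed trace itself; configurable), applies a 1 ms lockout,
re-aligns each event to its local minimum and cuts a 1 + 2 ms snippet.
Firing rates are counts over segment durations; epochs contain six 3 s
stimulation trials on a 20 s cycle plus four 3 s baseline segments (two
immediately before the first trial, two after the last — per-condition
bookkeeping of the "two prior / two after" rule).  The rhythmicity index
folds spike times on the 50 ms photostimulation period and returns the
fraction in the 25 ms ON phase (1 locked, 0.5 unlocked, 0 anti-locked);
segments from channels ≥ 150 um from the illumination edge are first
shifted back by 3 ms to compensate the propagation delay.  Waveform
features are valley-to-peak width and |valley|/|peak| from the averaged,
amplitude-window-filtered detections (events within ±35% of the modal
amplitude); width > 0.55 ms (strict) classifies a unit as regular-spiking,
otherwise fast-spiking.  Peristimulus phase histograms use 1 ms bins; the
first peak is the earliest local maximum at least twice the mean bin
count, and propagation speed is electrode separation over the difference
of two first-peak latencies.  The [K+]o threshold is the 50% point of a
2-parameter logistic (asymptotes 0 and 1, the data being cumulative
proportions) fitted by least squares.  Effects are summarised by the
bootstrap percentile CI of the median difference (the estimation-
statistics convention) and the tie-corrected, continuity-corrected
rank-sum z.  No multiple-testing correction is applied (single planned
comparisons).

## The synthetic-recording generator

`synth` renders 16-channel, 25 kHz recordings with 100 um spacing: white
Gaussian noise (an ideal 300 Hz high-pass is assumed — no line noise,
drift, or electrode filtering), plus spike templates at ground-truth
times.  Channels in the illuminated span fire 4 locked spikes per 25 ms
ON pulse (first at 4 ms phase, 2.5 ms intra-burst interval, 0.5 ms
Gaussian jitter); channels beyond the span fire one locked spike per
pulse only when propagation is enabled and they lie within the
propagation extent, delayed by distance/speed.  All channels carry
Poisson background spiking whose rate grows by 1 Hz per mM of [K+]o
above 3.5 mM.  Templates are difference-of-Gaussian biphasic waveforms,
valley-normalised: FS 0.30 ms valley-to-peak with a prominent overshoot,
RS 0.80 ms with a smaller one; default amplitude is 8 noise SDs.  The
threshold-dataset generator draws each synthetic slice's propagation
onset from a logistic (location 8.0 mM, slope 1.5/mM by default) and
reports cumulative proportions across the tested [K+]o levels.

What passing the synthetic suite shows: the pipeline recovers injected
unit classes (≥ 95% at SNR 8), injected propagation speeds over
20–100 mm/s within one histogram bin of latency, and the injected
logistic threshold within 0.5 mM at 24 slices.  What it does not show:
robustness to real recording artefacts (drift, line noise, overlapping
units, electrode impedance variation), nor the experimental values
themselves — the experimental estimates (8.0 mM threshold, 59.1 mm/s
median, 45.3% of slices propagating) require the raw recordings and are
covered here only as generator settings recovered by the pipeline.

## Problem sizes

Default analysis scale: 200 long propagations per condition for the
headline medians (the test suite uses 30, which is stable to a few mm/s);
synthetic recordings of one or two 20 s stimulation cycles for pipeline
tests; 40,000 bootstrap resamples when comparing against exhaustive
enumeration at n = 5.

## Known limitations

* The channel kinetics are a stand-in for the cited base model; the
  quantitative simulation medians are contingent on them (the condition
  *orderings* are robust across every kinetics variant explored).
* No axons, chemical synapses, extracellular-field forward modelling, ion
  accumulation, or temperature scaling of rates.
* The high-K+ condition models only the E_K/leak shift, not K+-dependent
  changes in channel gating or transporter function.
* The MEA generator and the network simulator are separate test surfaces
  by design; no extracellular forward model links them.
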