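# gjprop

Biophysical simulation and electrophysiological analysis of activity
propagating through the gap-junction-coupled network (syncytium) of
fast-spiking, parvalbumin-positive (PV) cortical interneurons.

Focal optogenetic activation of PV interneurons normally drives spiking
only under the light spot.  When extracellular potassium rises — as it
does during intense network activity and seizures — time-locked
fast-spiking unit activity appears at electrodes hundreds of micrometres
away, propagating through the PV syncytium at tens of mm/s.  This package
implements the two computational halves of that study, for computational
neuroscientists and electrophysiologists:

1. **Network simulation** (`gjprop.cell`, `gjprop.network`,
   `gjprop.propagation`): seventy three-compartment Hodgkin–Huxley-type
   FS interneurons scattered in a 650 × 150 × 150 μm virtual slice,
   connected by dendro-dendritic gap junctions (g_gap = 0.3 nS, at most
   one per pair, connection probability decaying linearly with distance),
   stimulated in the leftmost 200 μm with 0.55 nA for 25 ms, under three
   conditions: control ([K⁺]ₒ = 3.5 mM), raised potassium
   ([K⁺]ₒ = 10.5 mM, which shifts E_K by (RT/F)·ln 3 ≈ +29 mV and
   depolarises rest), and 4-AP (K⁺ conductances at 2%, membrane
   resistance ×5).  Propagation speed follows the first-wave definition:
   Δx/Δt between the first spikes of the last stimulated and last
   recruited cells.
2. **Multiunit-activity (MUA) analysis** (`gjprop.mua`) with a
   ground-truth synthetic recording generator (`gjprop.synth`):
   4·SD spike detection, per-segment firing rates, the ON-phase
   rhythmicity index of the 20 Hz / 50% duty photostimulation, valley-to-
   peak waveform classification (regular-spiking iff width > 0.55 ms),
   peristimulus-histogram first-peak latencies and the derived
   propagation speed, the sigmoidal [K⁺]ₒ-threshold fit, bootstrap
   median-difference CIs and the tie-corrected rank-sum z.

The two halves are deliberately independent: the simulator is scored by
its emergent propagation statistics, the MUA pipeline by its recovery of
parameters injected into synthetic 16-channel, 25 kHz recordings.
Channel kinetics for the cell model are a documented, configurable
stand-in set (see `docs/methods.md`); the quantitative simulation medians
are contingent on it, the condition contrasts are not.

## Worked example

```python
from gjprop import condition, build_network, simulate_network
from gjprop.propagation import summarize_run

net = build_network(n=70, seed=5)            # placement + gap junctions
for label in ("control", "high_k", "four_ap"):
    s = summarize_run(simulate_network(net, condition(label)))
    print(f"{label:8s} reached={s.reached_id:2d} long={s.is_long!s:5s} "
          f"speed={s.speed_mm_s:6.1f} mm/s participation={s.participation_pct:5.1f}%")
```

prints (speeds in mm/s; `nan` where nothing left the stimulated zone):

```
control  reached=20 long=False speed=   nan mm/s participation=  0.0%
high_k   reached=62 long=True  speed=  59.2 mm/s participation= 54.0%
four_ap  reached=70 long=True  speed=  41.7 mm/s participation=100.0%
```

`reached` is the largest cell id (x-rank of 70) with a post-onset spike
and `long=True` marks propagations reaching cell 60 or beyond — the
events that enter the headline medians.

— the single-run view of the condition contrast: control activity stays
inside the stimulated zone; raised [K⁺]ₒ yields a fast but sparse
propagation that can fail before the slice end; 4-AP yields a slower
propagation that recruits every cell.  The numbered drivers under
`analysis/` walk through the full study: single-cell characterisation,
example rasters, the 200-propagation condition experiment, the MUA
pipeline on a synthetic 59.1 mm/s recording, and the [K⁺]ₒ-threshold
fit; each writes its tables and figures to `results/`.

A command-line entry point wraps the same functions:

```sh
gjprop simulate --condition high_k --seed 7 --out runs/hk7
gjprop experiment --condition 4ap --n-long 200 --seed 1 --out fourap.csv
gjprop synth --speed 60 --k 9.5 --seed 3 --out rec.h5
gjprop analyze --recording rec.h5 --out channels.csv
```

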