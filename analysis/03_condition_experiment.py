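"""The condition-contrast experiment: speed and participation distributions.

Repeats random-network simulations under high [K+]o and 4-AP until the
first N long propagations per condition (default 200, as in the headline
analysis; pass a smaller N as argv[1] for a quick look), compares the two
conditions with the two-sided rank-sum test, and writes the run tables and
box plots under results/.
"""

import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from gjprop.propagation import compare_conditions, run_condition_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    n_long = int(sys.argv[1]) if len(sys.argv) > 1 else 200
    results = {}
    for label, seed in (("high_k", 11), ("four_ap", 12)):
        print(f"collecting {n_long} long propagations under {label} ...",
              flush=True)
        res = run_condition_experiment(label, n_long=n_long, seed=seed,
                                       progress=True)
        res.table.to_csv(OUT / f"experiment_{label}.csv", index=False)
        results[label] = res
        print(f"  {res.n_long} long / {len(res.table)} runs; "
              f"median speed {res.median_speed_mm_s:.1f} mm/s; "
              f"median participation {res.median_participation_pct:.1f}%")

    speed_cmp = compare_conditions(results["high_k"], results["four_ap"],
                                   "speed_mm_s")
    part_cmp = compare_conditions(results["four_ap"], results["high_k"],
                                  "participation_pct")
    print(f"speed, high-K vs 4-AP: z = {speed_cmp['z']:.2f}, "
          f"p = {speed_cmp['p']:.2g}")
    print(f"participation, 4-AP vs high-K: z = {part_cmp['z']:.2f}, "
          f"p = {part_cmp['p']:.2g}")

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, col, title in ((axes[0], "speed_mm_s", "propagation speed (mm/s)"),
                           (axes[1], "participation_pct", "participation (%)")):
        data = [results["high_k"].long_table[col].dropna(),
                results["four_ap"].long_table[col].dropna()]
        ax.boxplot(data, tick_labels=["high K+", "4-AP"])
        ax.set_ylabel(title)
    fig.tight_layout()
    fig.savefig(OUT / "condition_experiment.png", dpi=150)


if __name__ == "__main__":
    main()
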