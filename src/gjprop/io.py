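"""Plain-text and HDF5 serialisation of networks, rasters and recordings.

Network descriptions are plain text (a placement table and a junction edge
list), spike rasters are two-column text (cell id, spike time in ms), and
voltage traces are columnar numeric text with a small header.  MEA
recordings go to HDF5 (trace matrix plus metadata attributes) with ground
truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .mua import MEARecording, StimTrain
from .network import CellPlacement, GapJunction, Network, SliceGeometry

__all__ = [
    "write_network", "read_network", "write_raster", "read_raster",
    "write_trace", "save_recording", "load_recording", "write_ground_truth",
]


def write_network(network: Network, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sl = network.placement.slice_geometry
    with open(d / "placement.tsv", "w") as fh:
        fh.write(f"# virtual slice {sl.x_um} x {sl.y_um} x {sl.z_um} um; "
                 "positions in um; id = x-rank\n")
        fh.write("id\tx_um\ty_um\tz_um\n")
        for i, (x, y, z) in enumerate(network.placement.xyz_um, start=1):
            fh.write(f"{i}\t{x:.4f}\t{y:.4f}\t{z:.4f}\n")
    with open(d / "junctions.tsv", "w") as fh:
        fh.write("# gap junctions: dendritic position in um from soma, "
                 "conductance in nS\n")
        fh.write("left_id\tright_id\tposition_um\tconductance_ns\n")
        for gj in network.junctions:
            fh.write(f"{gj.left_id}\t{gj.right_id}\t{gj.position_um:.4f}"
                     f"\t{gj.conductance_ns:.6g}\n")


def read_network(directory: str | Path) -> Network:
    d = Path(directory)
    plc = np.loadtxt(d / "placement.tsv", skiprows=2)
    plc = np.atleast_2d(plc)
    header = open(d / "placement.tsv").readline().split()
    sl = SliceGeometry(float(header[3]), float(header[5]), float(header[7]))
    placement = CellPlacement(xyz_um=plc[:, 1:4], slice_geometry=sl)
    jraw = np.loadtxt(d / "junctions.tsv", skiprows=2, ndmin=2)
    junctions = tuple(
        GapJunction(int(r[0]), int(r[1]), float(r[2]), float(r[3]))
        for r in jraw)
    return Network(placement=placement, junctions=junctions)


def write_raster(spike_times_ms: list[np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tspike_time_ms\n")
        for i, st in enumerate(spike_times_ms, start=1):
            for t in st:
                fh.write(f"{i}\t{t:.3f}\n")


def read_raster(path: str | Path, n_cells: int) -> list[np.ndarray]:
    raw = np.loadtxt(path, skiprows=1, ndmin=2)
    out = [np.empty(0) for _ in range(n_cells)]
    if raw.size:
        for i in range(n_cells):
            out[i] = np.sort(raw[raw[:, 0] == i + 1, 1])
    return out


def write_trace(time_ms: np.ndarray, v_mv: np.ndarray, path: str | Path,
                label: str = "segment") -> None:
    """Columnar voltage trace: time then one column per recorded segment."""
    cols = np.column_stack([time_ms, np.atleast_2d(v_mv).T])
    header = "time_ms\t" + "\t".join(
        f"{label}{i}_mv" for i in range(np.atleast_2d(v_mv).shape[0]))
    np.savetxt(path, cols, fmt="%.6g", delimiter="\t", header=header,
               comments="")


def save_recording(rec: MEARecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("traces", data=rec.traces, compression="gzip")
        ds.attrs["fs_hz"] = rec.fs_hz
        ds.attrs["spacing_um"] = rec.spacing_um
        ds.attrs["illuminated"] = rec.illuminated
        ds.attrs["k_out_mm"] = rec.k_out_mm
        ds.attrs["condition"] = rec.condition
        for k in ("cycle_s", "stim_s", "pulse_hz", "duty", "n_trials",
                  "first_onset_s"):
            ds.attrs[f"stim_{k}"] = getattr(rec.stim, k)


def load_recording(path: str | Path) -> MEARecording:
    with h5py.File(path, "r") as f:
        ds = f["traces"]
        a = ds.attrs
        stim = StimTrain(cycle_s=float(a["stim_cycle_s"]),
                         stim_s=float(a["stim_stim_s"]),
                         pulse_hz=float(a["stim_pulse_hz"]),
                         duty=float(a["stim_duty"]),
                         n_trials=int(a["stim_n_trials"]),
                         first_onset_s=float(a["stim_first_onset_s"]))
        return MEARecording(traces=ds[...], fs_hz=float(a["fs_hz"]),
                            spacing_um=float(a["spacing_um"]),
                            illuminated=tuple(int(x) for x in a["illuminated"]),
                            stim=stim, k_out_mm=float(a["k_out_mm"]),
                            condition=str(a["condition"]))


def write_ground_truth(gt, path: str | Path) -> None:
    payload = {
        "unit_class": gt.unit_class,
        "delay_ms": gt.delay_ms.tolist(),
        "locked": gt.locked.astype(int).tolist(),
        "speed_mm_s": gt.config.speed_mm_s,
        "extent_um": gt.config.extent_um,
        "propagation": gt.config.propagation,
        "k_out_mm": gt.config.k_out_mm,
        "seed": gt.config.seed,
        "locked_times_s": [t.tolist() for t in gt.locked_times_s],
    }
    Path(path).write_text(json.dumps(payload))
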