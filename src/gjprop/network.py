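"""Virtual-slice construction and coupled-network simulation.

Seventy identical model cells are scattered uniformly in a
650 x 150 x 150 um virtual slice.  Cell ids are x-ranks (1 = leftmost).
Pairs are connected by at most one gap junction with probability falling
linearly with somatic distance (zero at 400 um, the summed length of the
two facing dendrites); a realised junction is placed symmetrically on the
left cell's right dendrite and the right cell's left dendrite, uniformly
between the closest geometrically possible point (half the inter-somatic
distance) and the dendritic tip.  Cells in the leftmost 200 um receive a
25 ms, 0.55 nA somatic pulse starting at t = 50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .cell import (
    N_SEG, SOMA_IDX, MechanismSet, ConditionSettings, apply_condition,
    build_cell_tables, build_gate_tables, initial_state,
)
from .errors import IntegrationDivergenceError
from .kinetics import KineticsParams

__all__ = [
    "SliceGeometry", "CellPlacement", "GapJunction", "StimulusProtocol",
    "Network", "SimulationResult", "place_cells", "connection_probability",
    "gap_junction_interval", "gap_junction_position", "build_connectivity",
    "build_network", "gap_current", "simulate_network",
]

DENDRITE_LENGTH_UM = 200.0
N_DEND_SEG = 10
SEG_LEN_UM = DENDRITE_LENGTH_UM / N_DEND_SEG
#: default connection probability at zero distance; together with the
#: stand-in channel kinetics this sets the network's propagation regime
#: (calibration documented in docs/methods.md)
DEFAULT_P0 = 0.48


@dataclass(frozen=True)
class SliceGeometry:
    x_um: float = 650.0
    y_um: float = 150.0
    z_um: float = 150.0

    def __post_init__(self):
        if min(self.x_um, self.y_um, self.z_um) <= 0:
            raise ValueError("slice extents must be positive")

    @property
    def volume_mm3(self) -> float:
        return self.x_um * self.y_um * self.z_um * 1e-9


@dataclass(frozen=True)
class CellPlacement:
    """Cell somata in the slice, ordered by x; id of row i is i + 1."""

    xyz_um: np.ndarray            # (n, 3), sorted on column 0
    slice_geometry: SliceGeometry

    @property
    def n(self) -> int:
        return self.xyz_um.shape[0]

    @property
    def x_um(self) -> np.ndarray:
        return self.xyz_um[:, 0]

    def distance(self, id_a: int, id_b: int) -> float:
        """3-D Euclidean somatic distance between two cells (ids 1-based)."""
        return float(np.linalg.norm(self.xyz_um[id_a - 1] - self.xyz_um[id_b - 1]))


@dataclass(frozen=True)
class GapJunction:
    """One electrical synapse between the facing dendrites of a pair."""

    left_id: int                  # smaller x
    right_id: int
    position_um: float            # distance from soma, same on both dendrites
    conductance_ns: float = 0.3

    def __post_init__(self):
        if self.left_id == self.right_id:
            raise ValueError("no self-junctions")
        if not (0 <= self.position_um <= DENDRITE_LENGTH_UM):
            raise ValueError("junction position outside the dendrite")
        if self.conductance_ns <= 0:
            raise ValueError("conductance must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    zone_x_max_um: float = 200.0
    amplitude_na: float = 0.55
    onset_ms: float = 50.0
    duration_ms: float = 25.0

    def __post_init__(self):
        if self.amplitude_na < 0 or self.onset_ms < 0 or self.duration_ms < 0:
            raise ValueError("stimulus parameters must be non-negative")

    def stimulated_ids(self, placement: CellPlacement) -> np.ndarray:
        """1-based ids of the cells inside the stimulated zone."""
        return np.nonzero(placement.x_um <= self.zone_x_max_um)[0] + 1


@dataclass(frozen=True)
class Network:
    placement: CellPlacement
    junctions: tuple[GapJunction, ...]
    seed: int | None = None


@dataclass
class SimulationResult:
    """Spike raster and (optionally) somatic voltage traces of one run."""

    spike_times_ms: list[np.ndarray]     # index i -> cell id i + 1
    network: Network
    condition_label: str
    stimulus: StimulusProtocol
    duration_ms: float
    dt_ms: float
    time_ms: np.ndarray | None = None
    v_soma_mv: np.ndarray | None = None  # (n_cells, n_t)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def place_cells(n: int, slice_geometry: SliceGeometry | None = None,
                seed: int | np.random.Generator | None = None) -> CellPlacement:
    """Scatter n cells i.i.d.-uniformly in the slice and rank them by x."""
    if n < 2:
        raise ValueError("need at least two cells")
    sl = slice_geometry or SliceGeometry()
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(0.0, 1.0, size=(n, 3)) * np.array([sl.x_um, sl.y_um, sl.z_um])
    xyz = xyz[np.argsort(xyz[:, 0], kind="stable")]
    return CellPlacement(xyz_um=xyz, slice_geometry=sl)


def connection_probability(d_um: float, p0: float = 1.0,
                           d_max_um: float = 2 * DENDRITE_LENGTH_UM) -> float:
    """Linearly distance-decaying connection probability, zero beyond d_max."""
    if not (0 <= p0 <= 1):
        raise ValueError("p0 must be in [0, 1]")
    if d_um < 0:
        raise ValueError("distance must be non-negative")
    return max(0.0, p0 * (1.0 - d_um / d_max_um))


def gap_junction_interval(d_um: float,
                          dendrite_length_um: float = DENDRITE_LENGTH_UM
                          ) -> tuple[float, float]:
    """Admissible dendritic placement interval [d/2, L] for a junction."""
    if d_um < 0:
        raise ValueError("distance must be non-negative")
    if d_um > 2 * dendrite_length_um:
        raise ValueError("pair not connectable: distance exceeds the two dendrites")
    return d_um / 2.0, dendrite_length_um


def gap_junction_position(d_um: float,
                          dendrite_length_um: float = DENDRITE_LENGTH_UM,
                          seed: int | np.random.Generator | None = None) -> float:
    """Uniform draw of the (symmetric) junction position from its interval."""
    lo, hi = gap_junction_interval(d_um, dendrite_length_um)
    rng = np.random.default_rng(seed)
    return float(rng.uniform(lo, hi))


def build_connectivity(placement: CellPlacement, p0: float = DEFAULT_P0,
                       d_max_um: float = 2 * DENDRITE_LENGTH_UM,
                       g_gap_ns: float = 0.3,
                       seed: int | np.random.Generator | None = None
                       ) -> tuple[GapJunction, ...]:
    """Independently connect each pair per the distance rule.

    Pairs are visited in fixed (left id, right id) order so that a given
    seed yields a bit-identical junction list.
    """
    rng = np.random.default_rng(seed)
    n = placement.n
    junctions = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = placement.distance(i + 1, j + 1)
            p = connection_probability(d, p0, d_max_um)
            if rng.uniform() < p and d <= 2 * DENDRITE_LENGTH_UM:
                lo, hi = gap_junction_interval(d)
                pos = float(rng.uniform(lo, hi))
                junctions.append(GapJunction(i + 1, j + 1, pos, g_gap_ns))
    return tuple(junctions)


def build_network(n: int = 70, slice_geometry: SliceGeometry | None = None,
                  p0: float = DEFAULT_P0, d_max_um: float = 2 * DENDRITE_LENGTH_UM,
                  g_gap_ns: float = 0.3, seed: int | None = None) -> Network:
    """Placement plus connectivity from one seed."""
    rng = np.random.default_rng(seed)
    placement = place_cells(n, slice_geometry, rng)
    junctions = build_connectivity(placement, p0, d_max_um, g_gap_ns, rng)
    return Network(placement=placement, junctions=junctions, seed=seed)


def gap_current(v_a_mv: float, v_b_mv: float, g_ns: float) -> tuple[float, float]:
    """Ohmic, non-rectifying junction currents (pA) into cells a and b."""
    if g_ns < 0:
        raise ValueError("conductance must be non-negative")
    i_a = g_ns * (v_b_mv - v_a_mv)    # nS * mV = pA
    return i_a, -i_a


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _junction_segment(position_um: float, side: str) -> int:
    """Chain index of the dendritic segment containing a junction.

    Chain layout: 0..9 left dendrite (distal -> proximal), 10 soma,
    11..20 right dendrite (proximal -> distal).
    """
    k = min(N_DEND_SEG - 1, int(position_um / SEG_LEN_UM))
    if side == "right":
        return SOMA_IDX + 1 + k
    return SOMA_IDX - 1 - k


def simulate_network(network: Network,
                     cond: ConditionSettings,
                     stim: StimulusProtocol | None = None,
                     duration_ms: float = 150.0,
                     dt_ms: float = 0.025,
                     mech: MechanismSet | None = None,
                     kin: KineticsParams | None = None,
                     v_init: float = -70.0,
                     record_soma: bool = False,
                     record_every: int = 20) -> SimulationResult:
    """Integrate the coupled network under a stimulation protocol.

    All cells share one mechanism set (after applying the condition) and
    identical geometry, so the cable tables are computed once.  The run is
    deterministic given the network and arguments.
    """
    stim = stim or StimulusProtocol()
    kin = kin if kin is not None else KineticsParams()
    mech = apply_condition(mech if mech is not None else MechanismSet(), cond)

    areas, gdens, gate_count, cm, ax_l, ax_r = build_cell_tables(mech)
    xinf, edt, v_lo, dv_inv = build_gate_tables(kin, dt_ms)

    nc = network.placement.n
    state = initial_state(mech, kin, v_init)
    V = np.tile(state.v, (nc, 1))
    gates = np.tile(state.gates, (nc, 1, 1))
    ca = np.full(nc, state.ca_mm)

    i_stim = np.zeros(nc)
    stim_ids = stim.stimulated_ids(network.placement)
    i_stim[stim_ids - 1] = stim.amplitude_na * 1e-3 / areas[SOMA_IDX]
    s_on = int(round(stim.onset_ms / dt_ms))
    s_off = int(round((stim.onset_ms + stim.duration_ms) / dt_ms))

    ngj = len(network.junctions)
    gj_ca = np.empty(ngj, dtype=np.int64)
    gj_sa = np.empty(ngj, dtype=np.int64)
    gj_cb = np.empty(ngj, dtype=np.int64)
    gj_sb = np.empty(ngj, dtype=np.int64)
    gj_gpa_a = np.empty(ngj)
    gj_gpa_b = np.empty(ngj)
    for k, gj in enumerate(network.junctions):
        gj_ca[k] = gj.left_id - 1
        gj_sa[k] = _junction_segment(gj.position_um, "right")
        gj_cb[k] = gj.right_id - 1
        gj_sb[k] = _junction_segment(gj.position_um, "left")
        g_ms = gj.conductance_ns * 1e-6
        gj_gpa_a[k] = g_ms / areas[gj_sa[k]]
        gj_gpa_b[k] = g_ms / areas[gj_sb[k]]

    nt = int(round(duration_ms / dt_ms))
    n_rec = nt // record_every if record_soma else 0
    v_rec = np.empty((nc, 1, max(n_rec, 1)))
    spk = np.empty((nc, 4000))
    spk_n = np.zeros(nc, dtype=np.int64)
    fail_cell = np.zeros(1, dtype=np.int64)

    status = _engine.run_network(
        nt, dt_ms, V, gates, ca, xinf, edt, v_lo, dv_inv,
        gdens, gate_count, cm, ax_l, ax_r,
        mech.e_na, mech.e_k, mech.e_ca, mech.e_h, mech.e_leak,
        SOMA_IDX, i_stim, s_on, s_off,
        gj_ca, gj_sa, gj_cb, gj_sb, gj_gpa_a, gj_gpa_b,
        kin.ca_depth_um, kin.ca_tau, kin.ca_rest, kin.fahp_kd_ca,
        spk, spk_n, v_rec, record_every if record_soma else 0, False,
        fail_cell)
    if status != 0:
        raise IntegrationDivergenceError(status * dt_ms, cell=int(fail_cell[0]) + 1)

    spikes = [spk[c, :min(spk_n[c], spk.shape[1])].copy() for c in range(nc)]
    time = (np.arange(n_rec) + 1) * record_every * dt_ms if record_soma else None
    return SimulationResult(
        spike_times_ms=spikes, network=network, condition_label=cond.label,
        stimulus=stim, duration_ms=duration_ms, dt_ms=dt_ms,
        time_ms=time, v_soma_mv=v_rec[:, 0, :] if record_soma else None)
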