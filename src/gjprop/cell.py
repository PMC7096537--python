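"""Single-cell biophysics of the three-compartment fast-spiking interneuron.

The model cell has one soma (27 x 29 um, one segment) and two identical
dendrites (200 x 0.8 um, ten segments each).  The soma carries transient
Na+, delayed-rectifier K+, A-type K+, slow (D-type) K+, N-type Ca2+,
H-current, a Ca2+-gated fast-AHP K+ current and a Ca2+ shell; the dendrites
carry only Na+, delayed-rectifier K+ and A-type K+.

Experimental conditions map onto parameters as follows:

* control    — default parameters, [K+]o = 3.5 mM;
* high_k     — [K+]o = 10.5 mM, shifting E_K by the Nernst relation and the
               leak reversal in proportion to the K+ fraction of the leak;
* four_ap    — membrane resistance x5 and every voltage-gated / Ca-gated K+
               conductance scaled to 2% of default (4-aminopyridine).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

from . import _engine
from .errors import IntegrationDivergenceError
from .kinetics import GATE_NAMES, KineticsParams, gate_inf_tau, gate_steady_state

__all__ = [
    "CompartmentGeometry", "MechanismSet", "ConditionSettings", "CellState",
    "CellTrace", "nernst_potential", "condition", "apply_condition",
    "default_geometry", "integrate_cell", "resting_potential", "rheobase",
]

GAS_CONSTANT = 8.314462618       # J / (mol K)
FARADAY = 96485.33212            # C / mol

#: reversal of the non-K+ leak component (mixed cation), mV.  Fixed so
#: that with the default K+ leak fraction the control leak reversal is
#: -69.8 mV and the control resting potential sits near -70 mV.
E_OTHER_MV = 41.45

DEFAULT_K_IN_MM = 140.0
DEFAULT_K_OUT_MM = 3.5
DEFAULT_TEMPERATURE_K = 307.15   # 34 C, mid-range of the recording bath
#: K+ fraction of the resting leak; sets how strongly raised [K+]o
#: depolarises the resting potential (see docs/methods.md)
DEFAULT_LEAK_K_FRACTION = 0.80

N_SEG = 21
SOMA_IDX = 10


def nernst_potential(k_out: float, k_in: float,
                     temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """K+ reversal potential (mV) from the Nernst equation.

    Parameters are the extracellular and intracellular K+ concentrations
    (mM, any common unit as long as they match) and the absolute
    temperature (K).
    """
    if k_out <= 0 or k_in <= 0 or temperature <= 0:
        raise ValueError("concentrations and temperature must be positive")
    return 1e3 * GAS_CONSTANT * temperature / FARADAY * math.log(k_out / k_in)


@dataclass(frozen=True)
class CompartmentGeometry:
    """One cylindrical compartment of the model cell."""

    name: str
    length_um: float
    diameter_um: float
    n_segments: int

    def __post_init__(self):
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("length and diameter must be positive")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


def default_geometry() -> tuple[CompartmentGeometry, ...]:
    return (
        CompartmentGeometry("dend_left", 200.0, 0.8, 10),
        CompartmentGeometry("soma", 27.0, 29.0, 1),
        CompartmentGeometry("dend_right", 200.0, 0.8, 10),
    )


def _control_e_k() -> float:
    return nernst_potential(DEFAULT_K_OUT_MM, DEFAULT_K_IN_MM)


def _leak_reversal(e_k: float, leak_k_fraction: float,
                   e_other: float = E_OTHER_MV) -> float:
    return leak_k_fraction * e_k + (1.0 - leak_k_fraction) * e_other


@dataclass(frozen=True)
class MechanismSet:
    """Maximal conductances (S/cm^2), passive properties and reversals.

    Defaults are the model's control values; the ``*_soma`` / ``*_dend``
    split mirrors the per-compartment conductance table.
    """

    g_na_soma: float = 0.045
    g_na_dend: float = 0.06
    g_kdr_soma: float = 0.018
    g_kdr_dend: float = 0.009
    g_ka_soma: float = 0.048
    g_ka_dend: float = 0.48
    g_kd_soma: float = 7.25e-5
    g_can_soma: float = 3e-4
    g_h_soma: float = 1e-5
    g_fahp_soma: float = 1e-4

    cm_uf_cm2: float = 1.2
    ra_ohm_cm: float = 150.0
    rm_kohm_cm2: float = 10.0

    e_na: float = 55.0
    e_k: float = field(default_factory=_control_e_k)
    e_ca: float = 120.0
    e_h: float = -30.0
    e_leak: float = field(
        default_factory=lambda: _leak_reversal(_control_e_k(),
                                               DEFAULT_LEAK_K_FRACTION))
    e_other: float = E_OTHER_MV

    def __post_init__(self):
        for name in ("g_na_soma", "g_na_dend", "g_kdr_soma", "g_kdr_dend",
                     "g_ka_soma", "g_ka_dend", "g_kd_soma", "g_can_soma",
                     "g_h_soma", "g_fahp_soma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cm_uf_cm2 <= 0 or self.ra_ohm_cm <= 0 or self.rm_kohm_cm2 <= 0:
            raise ValueError("passive properties must be positive")


@dataclass(frozen=True)
class ConditionSettings:
    """Experimental condition and its parameter mapping."""

    label: str
    k_out_mm: float
    k_in_mm: float = DEFAULT_K_IN_MM
    temperature_k: float = DEFAULT_TEMPERATURE_K
    leak_k_fraction: float = DEFAULT_LEAK_K_FRACTION
    rm_multiplier: float = 1.0
    k_conductance_scale: float = 1.0

    def __post_init__(self):
        if self.label not in ("control", "high_k", "four_ap"):
            raise ValueError(f"unknown condition label {self.label!r}")
        if self.k_out_mm <= 0 or self.k_in_mm <= 0:
            raise ValueError("K+ concentrations must be positive")
        if self.rm_multiplier < 1:
            raise ValueError("rm_multiplier must be >= 1")
        if not (0 < self.k_conductance_scale <= 1):
            raise ValueError("k_conductance_scale must be in (0, 1]")
        if not (0 <= self.leak_k_fraction <= 1):
            raise ValueError("leak_k_fraction must be in [0, 1]")


_CONDITIONS = {
    "control": dict(k_out_mm=3.5),
    "high_k": dict(k_out_mm=10.5),
    "four_ap": dict(k_out_mm=3.5, rm_multiplier=5.0, k_conductance_scale=0.02),
}


def condition(label: str, **overrides) -> ConditionSettings:
    """Build the settings of one of the three experimental conditions."""
    if label not in _CONDITIONS:
        raise ValueError(f"unknown condition label {label!r}")
    kw = dict(_CONDITIONS[label])
    kw.update(overrides)
    return ConditionSettings(label=label, **kw)


def apply_condition(base: MechanismSet, cond: ConditionSettings) -> MechanismSet:
    """Map a condition onto the mechanism set.

    high_k replaces E_K by the Nernst value at the raised [K+]o and moves
    the leak reversal toward the new E_K in proportion to the K+ fraction
    of the leak.  four_ap multiplies R_m by the stated factor and scales
    every K+ conductance (delayed rectifier, A-type, D-type, fAHP).
    Non-K+ mechanisms are untouched; control is the identity.
    """
    e_k = nernst_potential(cond.k_out_mm, cond.k_in_mm, cond.temperature_k)
    s = cond.k_conductance_scale
    return replace(
        base,
        e_k=e_k,
        e_leak=_leak_reversal(e_k, cond.leak_k_fraction, base.e_other),
        rm_kohm_cm2=base.rm_kohm_cm2 * cond.rm_multiplier,
        g_kdr_soma=base.g_kdr_soma * s,
        g_kdr_dend=base.g_kdr_dend * s,
        g_ka_soma=base.g_ka_soma * s,
        g_ka_dend=base.g_ka_dend * s,
        g_kd_soma=base.g_kd_soma * s,
        g_fahp_soma=base.g_fahp_soma * s,
    )


@dataclass
class CellState:
    """Instantaneous state of one cell: per-segment voltage, gates, Ca."""

    v: np.ndarray                 # (n_seg,), mV
    gates: np.ndarray             # (n_seg, n_gates), each in [0, 1]
    ca_mm: float                  # somatic shell Ca2+, mM


@dataclass
class CellTrace:
    """Result of a single-cell integration."""

    time_ms: np.ndarray           # (n_t,)
    v_mv: np.ndarray              # (n_rec_seg, n_t)
    spike_times_ms: np.ndarray    # somatic threshold crossings


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

def build_cell_tables(mech: MechanismSet,
                      geometry: tuple[CompartmentGeometry, ...] | None = None):
    """Discretise the cell into per-segment arrays for the integrator.

    Returns (areas_cm2, gdens, cm, ax_l, ax_r) where gdens is the
    (n_seg, 8) conductance-density table in mS/cm^2 (channel order
    Na, Kdr, KA, KD, CaN, H, fAHP, leak) and ax_l/ax_r the per-area axial
    couplings (mS/cm^2) to the left/right neighbour along the
    dendrite-soma-dendrite chain.
    """
    geometry = geometry or default_geometry()
    if [g.name for g in geometry] != ["dend_left", "soma", "dend_right"]:
        raise ValueError("geometry must be (dend_left, soma, dend_right)")
    dl, soma, dr = geometry
    if soma.n_segments != 1:
        raise ValueError("the soma is a single segment")

    seg_len = []
    seg_diam = []
    for comp, reverse in ((dl, True), (soma, False), (dr, False)):
        lengths = [comp.length_um / comp.n_segments] * comp.n_segments
        for L in lengths:
            seg_len.append(L)
            seg_diam.append(comp.diameter_um)
    seg_len = np.array(seg_len)
    seg_diam = np.array(seg_diam)
    nseg = len(seg_len)
    soma_idx = dl.n_segments

    areas_cm2 = np.pi * seg_diam * seg_len * 1e-8
    radius_cm = seg_diam / 2 * 1e-4
    len_cm = seg_len * 1e-4
    # half-resistance from a segment centre to its boundary, Ohm
    r_half = mech.ra_ohm_cm * (len_cm / 2) / (np.pi * radius_cm**2)
    g_ax_ms = 1e3 / (r_half[:-1] + r_half[1:])   # mS between centres

    ax_l = np.zeros(nseg)
    ax_r = np.zeros(nseg)
    ax_l[1:] = g_ax_ms / areas_cm2[1:]
    ax_r[:-1] = g_ax_ms / areas_cm2[:-1]

    gdens = np.zeros((nseg, 8))
    dend = np.ones(nseg, dtype=bool)
    dend[soma_idx] = False
    gdens[dend, _engine.CH_NA] = mech.g_na_dend * 1e3
    gdens[dend, _engine.CH_KDR] = mech.g_kdr_dend * 1e3
    gdens[dend, _engine.CH_KA] = mech.g_ka_dend * 1e3
    gdens[soma_idx, _engine.CH_NA] = mech.g_na_soma * 1e3
    gdens[soma_idx, _engine.CH_KDR] = mech.g_kdr_soma * 1e3
    gdens[soma_idx, _engine.CH_KA] = mech.g_ka_soma * 1e3
    gdens[soma_idx, _engine.CH_KD] = mech.g_kd_soma * 1e3
    gdens[soma_idx, _engine.CH_CAN] = mech.g_can_soma * 1e3
    gdens[soma_idx, _engine.CH_H] = mech.g_h_soma * 1e3
    gdens[soma_idx, _engine.CH_FAHP] = mech.g_fahp_soma * 1e3
    gdens[:, _engine.CH_LEAK] = 1.0 / mech.rm_kohm_cm2   # mS/cm^2

    cm = np.full(nseg, mech.cm_uf_cm2)
    # gates m,h,n,a,b live on every segment; d,c,r only where the D-type,
    # N-type Ca or H mechanisms are present (the soma)
    gate_count = np.where(gdens[:, 3:6].sum(axis=1) > 0, 8, 5).astype(np.int64)
    return areas_cm2, gdens, gate_count, cm, ax_l, ax_r


def build_gate_tables(kin: KineticsParams, dt: float,
                      v_lo: float = -130.0, v_hi: float = 70.0,
                      dv: float = 0.05):
    """Tabulate gate steady states and exp(-dt/tau) on a voltage grid."""
    v = np.arange(v_lo, v_hi + dv / 2, dv)
    xinf = np.empty((v.size, len(GATE_NAMES)))
    edt = np.empty_like(xinf)
    for i, g in enumerate(GATE_NAMES):
        gi, tau = gate_inf_tau(g, v, kin)
        xinf[:, i] = gi
        edt[:, i] = np.exp(-dt / tau)
    if kin.na_m_instantaneous:
        edt[:, 0] = 0.0
    return xinf, edt, v_lo, 1.0 / dv


def initial_state(mech: MechanismSet, kin: KineticsParams,
                  v_init: float = -70.0) -> CellState:
    gates = np.tile(gate_steady_state(v_init, kin), (N_SEG, 1))
    return CellState(v=np.full(N_SEG, v_init), gates=gates, ca_mm=kin.ca_rest)


# ---------------------------------------------------------------------------
# single-cell integration (one-cell network, no junctions)
# ---------------------------------------------------------------------------

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


def integrate_cell(mech: MechanismSet | None = None,
                   kin: KineticsParams | None = None,
                   i_amp_na: float = 0.0,
                   i_onset_ms: float = 50.0,
                   i_dur_ms: float = 25.0,
                   duration_ms: float = 300.0,
                   dt_ms: float = 0.025,
                   v_init: float = -70.0,
                   record: str = "soma",
                   record_every: int = 4) -> CellTrace:
    """Integrate one cell with a somatic current pulse.

    ``i_amp_na`` is the pulse amplitude in nA injected at the soma between
    ``i_onset_ms`` and ``i_onset_ms + i_dur_ms``.  ``record`` selects the
    recorded voltages ("soma" or "all" segments), sampled every
    ``record_every`` time steps.
    """
    if dt_ms <= 0 or duration_ms <= 0:
        raise ValueError("dt and duration must be positive")
    mech = mech if mech is not None else MechanismSet()
    kin = kin if kin is not None else KineticsParams()

    areas, gdens, gate_count, cm, ax_l, ax_r = build_cell_tables(mech)
    xinf, edt, v_lo, dv_inv = build_gate_tables(kin, dt_ms)

    nt = int(round(duration_ms / dt_ms))
    state = initial_state(mech, kin, v_init)
    V = state.v[None, :].copy()
    gates = state.gates[None, :, :].copy()
    ca = np.array([state.ca_mm])

    i_stim = np.array([i_amp_na * 1e-3 / areas[SOMA_IDX]])   # uA/cm^2
    s_on = int(round(i_onset_ms / dt_ms))
    s_off = int(round((i_onset_ms + i_dur_ms) / dt_ms))

    rec_all = record == "all"
    n_rec = nt // record_every
    v_rec = np.empty((1, N_SEG if rec_all else 1, n_rec))
    spk = np.empty((1, 4000))
    spk_n = np.zeros(1, dtype=np.int64)

    status = _engine.run_network(
        nt, dt_ms, V, gates, ca, xinf, edt, v_lo, dv_inv,
        gdens, gate_count, cm, ax_l, ax_r,
        mech.e_na, mech.e_k, mech.e_ca, mech.e_h, mech.e_leak,
        SOMA_IDX, i_stim, s_on, s_off,
        _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_F, _EMPTY_F,
        kin.ca_depth_um, kin.ca_tau, kin.ca_rest, kin.fahp_kd_ca,
        spk, spk_n, v_rec, record_every, rec_all,
        np.zeros(1, dtype=np.int64))
    if status != 0:
        raise IntegrationDivergenceError(status * dt_ms)

    t = (np.arange(n_rec) + 1) * record_every * dt_ms
    return CellTrace(time_ms=t, v_mv=v_rec[0],
                     spike_times_ms=spk[0, :min(spk_n[0], spk.shape[1])].copy())


def resting_potential(mech: MechanismSet | None = None,
                      kin: KineticsParams | None = None,
                      settle_ms: float = 500.0, dt_ms: float = 0.025) -> float:
    """Somatic resting potential after settling with zero input, mV."""
    tr = integrate_cell(mech, kin, i_amp_na=0.0, duration_ms=settle_ms,
                        dt_ms=dt_ms)
    if tr.spike_times_ms.size:
        raise RuntimeError("cell is not quiescent at rest")
    return float(tr.v_mv[0, -1])


def rheobase(mech: MechanismSet | None = None,
             kin: KineticsParams | None = None,
             pulse_ms: float = 25.0, lo_na: float = 0.0, hi_na: float = 2.0,
             tol_na: float = 0.005) -> float:
    """Minimal 25 ms somatic pulse amplitude (nA) that elicits a spike."""
    mech = mech if mech is not None else MechanismSet()

    def fires(amp):
        tr = integrate_cell(mech, kin, i_amp_na=amp, i_onset_ms=100.0,
                            i_dur_ms=pulse_ms, duration_ms=100.0 + pulse_ms + 25.0)
        return np.any(tr.spike_times_ms >= 100.0)

    if not fires(hi_na):
        raise ValueError(f"no spike even at {hi_na} nA")
    while hi_na - lo_na > tol_na:
        mid = 0.5 * (lo_na + hi_na)
        if fires(mid):
            hi_na = mid
        else:
            lo_na = mid
    return 0.5 * (lo_na + hi_na)
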