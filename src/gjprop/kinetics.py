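"""Channel gating kinetics for the fast-spiking interneuron model.

The network model uses a three-compartment parvalbumin-positive (PV)
fast-spiking interneuron with Hodgkin–Huxley-style mechanisms.  The spiking
core (transient Na+ and delayed-rectifier K+) follows the classic
fast-spiking interneuron formulation of Wang & Buzsaki (J Neurosci 1996);
the remaining mechanisms (A-type K+, slow/D-type K+, N-type Ca2+, H-current,
Ca2+-gated fast-afterhyperpolarisation K+) use standard first-order Boltzmann
activation/inactivation forms.  Every rate parameter is carried in
:class:`KineticsParams` so an alternative kinetics set can be substituted
without touching the integrator.

Voltage in mV, time in ms, Ca2+ in mM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
import numpy as np

__all__ = ["KineticsParams", "gate_steady_state", "GATE_NAMES"]

#: order of the gating variables as stored by the integrator
GATE_NAMES = ("m", "h", "n", "a", "b", "d", "c", "r")


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 handled."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 + x / (2.0 * y)), x / (1.0 - np.exp(-np.clip(x / y, -500, 500))))
    return out


@dataclass
class KineticsParams:
    """Rate constants of all gating variables.

    The defaults constitute the package's documented stand-in kinetics set
    for a cortical fast-spiking interneuron; see docs/methods.md for the
    full equations and the calibration rationale.
    """

    # temperature-like rate scale applied to Na inactivation and K-dr
    # activation (Wang-Buzsaki phi)
    phi: float = 5.0

    # -- transient Na+ (gates m^3 h) ---------------------------------------
    # The +6 mV activation shift sets the spike threshold near -48 mV and
    # the +4 mV inactivation shift the availability curve; together they
    # place the coupled network in the propagation regime described in
    # docs/methods.md (calibration of the stand-in kinetics).
    na_m_vshift: float = 6.0     # additive shift on the m rate curves, mV
    na_h_vshift: float = 4.0
    #: Wang-Buzsaki convention: m relaxes fast and is set to its steady
    #: state every step (required for spike generation at phi = 5)
    na_m_instantaneous: bool = True

    # -- delayed rectifier K+ (n^4) ----------------------------------------
    kdr_n_vshift: float = 0.0

    # -- A-type K+ (a^3 * b) -----------------------------------------------
    ka_va: float = -20.0         # activation half-voltage, mV
    ka_ka: float = 12.0          # activation slope, mV
    ka_tau_a: float = 2.0        # activation time constant, ms
    ka_vb: float = -70.0         # inactivation half-voltage, mV
    ka_kb: float = 7.0           # inactivation slope, mV
    ka_tau_b: float = 20.0       # inactivation time constant, ms

    # -- slow / D-type K+ (d) ----------------------------------------------
    kd_vd: float = -43.0
    kd_kd: float = 8.0
    kd_tau_d: float = 80.0

    # -- N-type high-threshold Ca2+ (c^2) ----------------------------------
    can_vc: float = -20.0
    can_kc: float = 7.0
    can_tau_c: float = 2.0

    # -- H-current (r) ------------------------------------------------------
    h_vr: float = -80.0
    h_kr: float = 8.0
    h_tau_r: float = 150.0

    # -- Ca2+-gated fAHP K+ (instantaneous o = Ca^2/(Ca^2+Kd^2)) -----------
    fahp_kd_ca: float = 1e-3     # half-activation Ca2+, mM

    # -- somatic Ca2+ shell -------------------------------------------------
    ca_depth_um: float = 0.1     # shell depth, um
    ca_tau: float = 20.0         # clearance time constant, ms
    ca_rest: float = 5e-5        # resting Ca2+, mM

    def to_array(self) -> np.ndarray:
        """Flatten to a float64 vector in field order, for the compiled kernel."""
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=np.float64)


# ---------------------------------------------------------------------------
# numpy reference implementations of the rate functions.  The compiled
# integrator re-implements these scalar-wise; tests assert agreement.
# ---------------------------------------------------------------------------

def na_m_rates(v, p: KineticsParams):
    vv = np.asarray(v, dtype=float) - p.na_m_vshift
    alpha = 0.1 * _vtrap(vv + 35.0, 10.0)
    beta = 4.0 * np.exp(-(vv + 60.0) / 18.0)
    return alpha, beta


def na_h_rates(v, p: KineticsParams):
    vv = np.asarray(v, dtype=float) - p.na_h_vshift
    alpha = p.phi * 0.07 * np.exp(-(vv + 58.0) / 20.0)
    beta = p.phi / (1.0 + np.exp(-(vv + 28.0) / 10.0))
    return alpha, beta


def kdr_n_rates(v, p: KineticsParams):
    vv = np.asarray(v, dtype=float) - p.kdr_n_vshift
    alpha = p.phi * 0.01 * _vtrap(vv + 34.0, 10.0)
    beta = p.phi * 0.125 * np.exp(-(vv + 44.0) / 80.0)
    return alpha, beta


def _boltzmann(v, vhalf, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vhalf) / k))


def gate_inf_tau(gate: str, v, p: KineticsParams):
    """Steady state and time constant of one gating variable at voltage v."""
    if gate == "m":
        a, b = na_m_rates(v, p)
    elif gate == "h":
        a, b = na_h_rates(v, p)
    elif gate == "n":
        a, b = kdr_n_rates(v, p)
    elif gate == "a":
        return _boltzmann(v, p.ka_va, p.ka_ka), np.full_like(np.asarray(v, dtype=float), p.ka_tau_a)
    elif gate == "b":
        return _boltzmann(v, p.ka_vb, -p.ka_kb), np.full_like(np.asarray(v, dtype=float), p.ka_tau_b)
    elif gate == "d":
        return _boltzmann(v, p.kd_vd, p.kd_kd), np.full_like(np.asarray(v, dtype=float), p.kd_tau_d)
    elif gate == "c":
        return _boltzmann(v, p.can_vc, p.can_kc), np.full_like(np.asarray(v, dtype=float), p.can_tau_c)
    elif gate == "r":
        return _boltzmann(v, p.h_vr, -p.h_kr), np.full_like(np.asarray(v, dtype=float), p.h_tau_r)
    else:
        raise ValueError(f"unknown gate {gate!r}")
    tau = 1.0 / (a + b)
    return a * tau, tau


def gate_steady_state(v: float, p: KineticsParams) -> np.ndarray:
    """Steady-state values of all gates at a fixed voltage (initialisation)."""
    out = np.empty(len(GATE_NAMES))
    for i, g in enumerate(GATE_NAMES):
        out[i], _ = gate_inf_tau(g, v, p)
    return out
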