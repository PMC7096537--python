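"""Compiled cable integrator for the coupled interneuron network.

One cell is a 21-segment unbranched chain (10 left-dendrite segments, soma,
10 right-dendrite segments), so each cell's cable matrix is tridiagonal and
is solved with the Thomas algorithm.  The scheme is a linearly implicit
trapezoid (Crank-Nicolson) step on the voltage with gating variables
advanced by exact exponential (Rush-Larsen) updates at the step midpoint,
per the staggered convention.  The Na+ activation gate, which is treated as
instantaneous, is corrected once against the midpoint voltage of a
predictor solve, keeping the spike times second-order accurate in dt.
Gap junctions couple cells semi-implicitly: a junction contributes its
conductance to the host segment's diagonal while the partner voltage enters
at the previous time step, which keeps the per-cell systems independent
(and the whole step O(n_cells * n_segments)).

Units: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2, mM.
"""

import numpy as np
from numba import njit

# channel order in the conductance-density table
CH_NA, CH_KDR, CH_KA, CH_KD, CH_CAN, CH_H, CH_FAHP, CH_LEAK = range(8)
N_GATES = 8  # m h n a b d c r

SPIKE_THRESHOLD_MV = 0.0
REFRACTORY_MS = 1.0

# Ca2+ shell flux conversion: dCa/dt [mM/ms] = -j[uA/cm^2] / (2*F*depth)
# with depth in um; 2*F*1e-4 cm/um scaling folded into the constant.
_CA_FLUX_DENOM = 2.0 * 96485.0 * 1e-4  # per um of depth


@njit(cache=True, inline="always")
def _interp(tab, i0, fr, g):
    return tab[i0, g] + (tab[i0 + 1, g] - tab[i0, g]) * fr


@njit(cache=True, inline="always")
def _table_index(v, v_lo, dv_inv, nv):
    idx = (v - v_lo) * dv_inv
    if idx < 0.0:
        idx = 0.0
    elif idx > nv - 2:
        idx = float(nv - 2)
    i0 = int(idx)
    return i0, idx - i0


@njit(cache=True)
def run_network(
    nt, dt,
    V, gates, ca,
    xinf_tab, edt_tab, v_lo, dv_inv,
    gdens, gate_count, cm, ax_l, ax_r,
    e_na, e_k, e_ca, e_h, e_leak,
    soma_idx,
    i_stim, s_on, s_off,
    gj_ca_idx, gj_sa, gj_cb_idx, gj_sb, gj_gpa_a, gj_gpa_b,
    ca_depth, ca_tau, ca_rest, fahp_kd,
    spk_times, spk_count,
    v_rec, rec_stride, rec_all,
    fail_cell,
    m_corrector=1,
):
    nc, nseg = V.shape
    nv = xinf_tab.shape[0]
    ngj = gj_ca_idx.shape[0]

    gj_diag = np.zeros((nc, nseg))
    gj_rhs = np.zeros((nc, nseg))
    Vnew = np.empty((nc, nseg))
    cp = np.empty(nseg)
    dp = np.empty(nseg)
    g_na_arr = np.empty(nseg)
    g_rest = np.empty(nseg)
    drive_rest = np.empty(nseg)
    last_spike = np.full(nc, -1e9)
    v_soma_prev = np.empty(nc)

    fahp_kd2 = fahp_kd * fahp_kd
    ca_flux_scale = 1.0 / (_CA_FLUX_DENOM * ca_depth)
    rec_i = 0

    for t in range(nt):
        tnow = (t + 1) * dt
        stim_on = (t >= s_on) and (t < s_off)

        # gap-junction contributions from previous-step partner voltages
        for c in range(nc):
            for s in range(nseg):
                gj_diag[c, s] = 0.0
                gj_rhs[c, s] = 0.0
        for k in range(ngj):
            a_c = gj_ca_idx[k]
            b_c = gj_cb_idx[k]
            a_s = gj_sa[k]
            b_s = gj_sb[k]
            gj_diag[a_c, a_s] += gj_gpa_a[k]
            gj_rhs[a_c, a_s] += gj_gpa_a[k] * V[b_c, b_s]
            gj_diag[b_c, b_s] += gj_gpa_b[k]
            gj_rhs[b_c, b_s] += gj_gpa_b[k] * V[a_c, a_s]

        for c in range(nc):
            v_soma_prev[c] = V[c, soma_idx]

            # midpoint gate update + split of conductances into the Na part
            # (subject to the m corrector) and the rest
            for s in range(nseg):
                v = V[c, s]
                i0, fr = _table_index(v, v_lo, dv_inv, nv)
                for g in range(gate_count[s]):
                    xi = _interp(xinf_tab, i0, fr, g)
                    ed = _interp(edt_tab, i0, fr, g)
                    gates[c, s, g] = xi + (gates[c, s, g] - xi) * ed

                m = gates[c, s, 0]
                h = gates[c, s, 1]
                n = gates[c, s, 2]
                aa = gates[c, s, 3]
                bb = gates[c, s, 4]
                dd = gates[c, s, 5]
                cc = gates[c, s, 6]
                rr = gates[c, s, 7]

                g_na_arr[s] = gdens[s, 0] * m * m * m * h
                g_kdr = gdens[s, 1] * n * n * n * n
                g_ka = gdens[s, 2] * aa * aa * aa * bb
                g_kd = gdens[s, 3] * dd
                g_can = gdens[s, 4] * cc * cc
                g_h = gdens[s, 5] * rr
                if gdens[s, 6] > 0.0:
                    ca2 = ca[c] * ca[c]
                    g_fahp = gdens[s, 6] * ca2 / (ca2 + fahp_kd2)
                else:
                    g_fahp = 0.0
                g_leak = gdens[s, 7]

                g_k_tot = g_kdr + g_ka + g_kd + g_fahp
                g_rest[s] = g_k_tot + g_can + g_h + g_leak
                drive_rest[s] = (g_k_tot * e_k + g_can * e_ca
                                 + g_h * e_h + g_leak * e_leak)

            # predictor (and, after the m correction, corrector) solves;
            # the corrector only runs while the cell's voltage is moving
            # fast (spike upstroke/downstroke), where the instantaneous
            # m gate's half-step lag matters
            for it in range(m_corrector + 1):
                if it == 1:
                    maxdv = 0.0
                    for s in range(nseg):
                        d_ = abs(Vnew[c, s] - V[c, s])
                        if d_ > maxdv:
                            maxdv = d_
                    if maxdv < 0.5:
                        break
                    # re-evaluate the instantaneous m gate at the midpoint
                    # voltage of the predictor solution
                    for s in range(nseg):
                        vm = 0.5 * (V[c, s] + Vnew[c, s])
                        i0, fr = _table_index(vm, v_lo, dv_inv, nv)
                        m = _interp(xinf_tab, i0, fr, 0)
                        gates[c, s, 0] = m
                        h = gates[c, s, 1]
                        g_na_arr[s] = gdens[s, 0] * m * m * m * h
                for s in range(nseg):
                    gtot = g_na_arr[s] + g_rest[s]
                    drive = g_na_arr[s] * e_na + drive_rest[s]
                    cdt = cm[s] / dt
                    g_self = gtot + ax_l[s] + ax_r[s] + gj_diag[c, s]
                    diag = cdt + 0.5 * g_self
                    rhs = (cdt - 0.5 * g_self) * V[c, s] + drive + gj_rhs[c, s]
                    if s > 0:
                        rhs += 0.5 * ax_l[s] * V[c, s - 1]
                    if s < nseg - 1:
                        rhs += 0.5 * ax_r[s] * V[c, s + 1]
                    if stim_on and s == soma_idx:
                        rhs += i_stim[c]
                    if s == 0:
                        cp[0] = 0.5 * ax_r[0] / diag
                        dp[0] = rhs / diag
                    else:
                        w = diag - 0.5 * ax_l[s] * cp[s - 1]
                        cp[s] = 0.5 * ax_r[s] / w
                        dp[s] = (rhs + 0.5 * ax_l[s] * dp[s - 1]) / w
                Vnew[c, nseg - 1] = dp[nseg - 1]
                for s in range(nseg - 2, -1, -1):
                    Vnew[c, s] = dp[s] + cp[s] * Vnew[c, s + 1]

        # commit, divergence check, Ca update, spike detection, recording
        for c in range(nc):
            for s in range(nseg):
                v = Vnew[c, s]
                if not np.isfinite(v) or v > 1e3 or v < -1e3:
                    fail_cell[0] = c
                    return t + 1
                V[c, s] = v

            # somatic Ca2+ shell driven by the N-type current at the new V
            cc = gates[c, soma_idx, 6]
            j_can = gdens[soma_idx, 4] * cc * cc * (V[c, soma_idx] - e_ca)
            influx = -j_can * ca_flux_scale
            if influx < 0.0:
                influx = 0.0
            ca[c] = (ca[c] + dt * (influx + ca_rest / ca_tau)) / (1.0 + dt / ca_tau)

            vs = V[c, soma_idx]
            if (vs >= SPIKE_THRESHOLD_MV and v_soma_prev[c] < SPIKE_THRESHOLD_MV
                    and tnow - last_spike[c] >= REFRACTORY_MS):
                # sub-step spike time by linear interpolation of the crossing
                frac = ((SPIKE_THRESHOLD_MV - v_soma_prev[c])
                        / (vs - v_soma_prev[c]))
                t_spk = t * dt + frac * dt
                last_spike[c] = t_spk
                if spk_count[c] < spk_times.shape[1]:
                    spk_times[c, spk_count[c]] = t_spk
                spk_count[c] += 1

        if rec_stride > 0 and (t + 1) % rec_stride == 0:
            if rec_i < v_rec.shape[2]:
                if rec_all:
                    for c in range(nc):
                        for s in range(nseg):
                            v_rec[c, s, rec_i] = V[c, s]
                else:
                    for c in range(nc):
                        v_rec[c, 0, rec_i] = V[c, soma_idx]
                rec_i += 1

    return 0
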