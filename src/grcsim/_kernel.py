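"""Fixed-step implicit integrator for the compartmental granule-cell model.

Numerical scheme (NEURON-like staggered theta-method):

* gate variables advance by the exact exponential update for the voltage
  frozen at the current step;
* the voltage equation, linear in V once gate values are fixed, is solved
  implicitly (theta = 0.5 -> Crank-Nicolson, theta = 1 -> backward Euler)
  with a Hines elimination on the compartment tree (parents precede
  children in the ordering);
* the Ca shell / CaM2C / TRPM4 states advance by forward-Euler / exponential
  updates; they are slow compared to dt.

Everything below is jitted; the pure-Python reference updates for the
calcium chain live in :mod:`grcsim.calcium` and the two are cross-checked
in the test suite.
"""

import math

import numpy as np
from numba import njit

# status codes returned by integrate()
OK = 0
CA_NEGATIVE = 1
V_BLOWUP = 2

# column layout of the gate-parameter matrix
GP_VHALF, GP_SLOPE, GP_FLOOR, GP_TAUMIN, GP_TAUAMP, GP_TAUVH, GP_TS1, GP_TS2, GP_EXP = range(9)

# channel kinds
KIND_HH = 0
KIND_CA_GATED = 1
KIND_CAM_GATED = 2
KIND_LEAK = 3

# aux column layout
AUX_CA, AUX_CAM2C, AUX_O, AUX_ITRPM4, AUX_ICLAMP = range(5)


@njit(cache=True)
def _hines_solve(parent, d, a, b, v_new, clamp_root, v_root):
    """Solve the symmetric tree-structured linear system in place.

    d: diagonal, a[i]: coupling of i with parent[i] (a[root] unused),
    b: RHS.  parent[i] < i for all non-root compartments.  If
    ``clamp_root`` the root voltage is constrained to ``v_root``.
    """
    n = d.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = a[i] / d[i]
        d[p] -= f * a[i]
        b[p] -= f * b[i]
    if clamp_root:
        v_new[0] = v_root
    else:
        v_new[0] = b[0] / d[0]
    for i in range(1, n):
        v_new[i] = (b[i] - a[i] * v_new[parent[i]]) / d[i]


@njit(cache=True)
def integrate(
    dt,
    nt,
    theta,
    parent,
    g_ax,
    cap,
    ch_comp,
    ch_g,
    ch_E,
    ch_kind,
    ch_gstart,
    ch_ng,
    ch_kd,
    ch_hill,
    ch_feeds,
    gp,
    gate_comp,
    v_init,
    m_init,
    state_init,
    ca_par,
    mode,
    i_inj,
    vcmd,
    syn_comp,
    g_ampa,
    g_nmda,
):
    """Integrate ``nt`` steps; returns (V[nt+1, ncomp], aux[nt+1, 5], status,
    status_comp).

    Units: V mV, t ms, conductances uS, capacitances nF, currents nA
    (i_inj at the soma, clamp current in aux), Ca/CaM concentrations nM.
    ``mode``: 0 current clamp, 1 somatic voltage clamp.
    """
    ncomp = parent.shape[0]
    nch = ch_comp.shape[0]
    nsc = syn_comp.shape[0]

    influx_fac = ca_par[0]
    k_ex = ca_par[1]
    ca_rest = ca_par[2]
    b_kon = ca_par[3]
    b_koff = ca_par[4]
    b_tot = ca_par[5]
    kon2 = ca_par[6]
    koff2 = ca_par[7]
    cam_tot = ca_par[8]
    thr = ca_par[9]
    hill_n = ca_par[10]
    tau_act = ca_par[11]
    tau_deact = ca_par[12]
    kca_tau = ca_par[14]

    v = v_init.copy()
    m = m_init.copy()
    ca = state_init[0]
    bound = state_init[1]
    cam2c = state_init[2]
    o_trpm4 = state_init[3]
    s_kca = state_init[4]
    o_kca = state_init[4]

    v_out = np.empty((nt + 1, ncomp))
    aux = np.zeros((nt + 1, 5))
    v_out[0] = v
    aux[0, AUX_CA] = ca
    aux[0, AUX_CAM2C] = cam2c
    aux[0, AUX_O] = o_trpm4

    G = np.empty(ncomp)
    S = np.empty(ncomp)
    d = np.empty(ncomp)
    bvec = np.empty(ncomp)
    a_off = np.empty(ncomp)
    v_new = np.empty(ncomp)
    open_frac = np.empty(nch)

    status = OK
    status_comp = -1

    # stagger gates by half a step (gate states then live at t_{n+1/2},
    # making the theta=0.5 voltage update second-order accurate)
    ng_total = gp.shape[0]
    for j in range(ng_total):
        vc = v[gate_comp[j]]
        minf = gp[j, GP_FLOOR] + (1.0 - gp[j, GP_FLOOR]) / (
            1.0 + math.exp(-(vc - gp[j, GP_VHALF]) / gp[j, GP_SLOPE])
        )
        bell = math.exp((vc - gp[j, GP_TAUVH]) / gp[j, GP_TS1]) + math.exp(
            -(vc - gp[j, GP_TAUVH]) / gp[j, GP_TS2]
        )
        tau = gp[j, GP_TAUMIN] + gp[j, GP_TAUAMP] / bell
        m[j] = minf + (m[j] - minf) * math.exp(-0.5 * dt / tau)

    for n in range(nt):
        # -- 1. gate update (exponential, V frozen at v) --------------------
        for j in range(ng_total):
            vc = v[gate_comp[j]]
            minf = gp[j, GP_FLOOR] + (1.0 - gp[j, GP_FLOOR]) / (
                1.0 + math.exp(-(vc - gp[j, GP_VHALF]) / gp[j, GP_SLOPE])
            )
            bell = math.exp((vc - gp[j, GP_TAUVH]) / gp[j, GP_TS1]) + math.exp(
                -(vc - gp[j, GP_TAUVH]) / gp[j, GP_TS2]
            )
            tau = gp[j, GP_TAUMIN] + gp[j, GP_TAUAMP] / bell
            m[j] = minf + (m[j] - minf) * math.exp(-dt / tau)

        # -- 2. Ca current feeding the shell (pA, electrophys sign) --------
        i_ca_pa = 0.0
        for c in range(nch):
            if ch_feeds[c] == 1:
                of = 1.0
                for k in range(ch_ng[c]):
                    j = ch_gstart[c] + k
                    of *= m[j] ** gp[j, GP_EXP]
                i_ca_pa += ch_g[c] * of * (v[ch_comp[c]] - ch_E[c]) * 1e3

        # -- 3. calcium / CaM2C / TRPM4 state updates -----------------------
        # exponential (Rush-Larsen) updates: each state is linear in itself
        # with the partner state frozen over the step
        influx = -i_ca_pa * influx_fac
        free_buf = b_tot - bound
        a_ca = influx + k_ex * ca_rest + b_koff * bound
        b_ca = k_ex + b_kon * free_buf
        ca_inf = a_ca / b_ca
        ca_new = ca_inf + (ca - ca_inf) * math.exp(-b_ca * dt)
        a_b = b_kon * ca * b_tot
        b_b = b_kon * ca + b_koff
        b_inf = a_b / b_b
        bound = b_inf + (bound - b_inf) * math.exp(-b_b * dt)
        ca = ca_new
        if ca < 0.0 or bound < 0.0 or bound > b_tot:
            status = CA_NEGATIVE
            status_comp = 0
            break
        a_c = kon2 * ca * ca * cam_tot
        b_c = kon2 * ca * ca + koff2
        c_inf = a_c / b_c
        cam2c = c_inf + (cam2c - c_inf) * math.exp(-b_c * dt)
        if thr > 0.0 and cam2c > 0.0:
            x = (cam2c / thr) ** hill_n
            o_inf = x / (1.0 + x)
        else:
            o_inf = 0.0
        tau_o = tau_act if o_inf > o_trpm4 else tau_deact
        o_trpm4 = o_inf + (o_trpm4 - o_inf) * math.exp(-dt / tau_o)
        # slow Ca-activated K gate: two-stage relaxation toward a Hill
        # function of shell Ca (sigmoidal onset: stable early response,
        # adaptation developing over seconds)
        kca_target = -1.0
        for c in range(nch):
            if ch_kind[c] == KIND_CA_GATED:
                xx = (ca / ch_kd[c]) ** ch_hill[c]
                kca_target = xx / (1.0 + xx)
                break
        if kca_target >= 0.0:
            stage_tau = 0.5 * kca_tau
            s_kca = kca_target + (s_kca - kca_target) * math.exp(-dt / stage_tau)
            o_kca = s_kca + (o_kca - s_kca) * math.exp(-dt / stage_tau)

        # -- 4. assemble per-compartment conductance G and source S ---------
        for i in range(ncomp):
            G[i] = 0.0
            S[i] = 0.0
        for c in range(nch):
            kind = ch_kind[c]
            if kind == KIND_HH:
                of = 1.0
                for k in range(ch_ng[c]):
                    j = ch_gstart[c] + k
                    of *= m[j] ** gp[j, GP_EXP]
            elif kind == KIND_CA_GATED:
                of = o_kca
            elif kind == KIND_CAM_GATED:
                of = o_trpm4
            else:  # leak
                of = 1.0
            open_frac[c] = of
            g = ch_g[c] * of
            i = ch_comp[c]
            G[i] += g
            S[i] += g * ch_E[c]
        # synapses (AMPA + Mg-blocked NMDA, E_rev = 0 mV)
        for sidx in range(nsc):
            i = syn_comp[sidx]
            blk = 1.0 / (1.0 + (1.0 / 3.57) * math.exp(-0.062 * v[i]))
            G[i] += g_ampa[n, sidx] + g_nmda[n, sidx] * blk

        # -- 5. implicit voltage update (theta method, Hines solve) ---------
        for i in range(ncomp):
            gax_sum = 0.0
            ax_rhs = 0.0
            if i > 0:
                gax_sum += g_ax[i]
                ax_rhs += g_ax[i] * (v[parent[i]] - v[i])
            for c2 in range(1, ncomp):
                if parent[c2] == i:
                    gax_sum += g_ax[c2]
                    ax_rhs += g_ax[c2] * (v[c2] - v[i])
            d[i] = cap[i] / dt + theta * (G[i] + gax_sum)
            bvec[i] = (
                cap[i] / dt * v[i]
                + S[i]
                - (1.0 - theta) * G[i] * v[i]
                + (1.0 - theta) * ax_rhs
            )
            a_off[i] = -theta * g_ax[i] if i > 0 else 0.0
        if mode == 0:
            bvec[0] += i_inj[n]
            _hines_solve(parent, d, a_off, bvec, v_new, False, 0.0)
        else:
            _hines_solve(parent, d, a_off, bvec, v_new, True, vcmd[n])

        # -- 6. clamp current / TRPM4 current bookkeeping -------------------
        i_trpm4_pa = 0.0
        for c in range(nch):
            if ch_kind[c] == KIND_CAM_GATED:
                i_trpm4_pa += (
                    ch_g[c] * open_frac[c] * (v_new[ch_comp[c]] - ch_E[c]) * 1e3
                )
        if mode == 1:
            vstar0 = theta * v_new[0] + (1.0 - theta) * v[0]
            ion0 = G[0] * vstar0 - S[0]
            ax0 = 0.0
            for c2 in range(1, ncomp):
                if parent[c2] == 0:
                    vstarc = theta * v_new[c2] + (1.0 - theta) * v[c2]
                    ax0 += g_ax[c2] * (vstarc - vstar0)
            i_clamp = cap[0] * (v_new[0] - v[0]) / dt + ion0 - ax0
        else:
            i_clamp = 0.0

        for i in range(ncomp):
            v[i] = v_new[i]
            if abs(v[i]) > 200.0:
                status = V_BLOWUP
                status_comp = i
        v_out[n + 1] = v
        aux[n + 1, AUX_CA] = ca
        aux[n + 1, AUX_CAM2C] = cam2c
        aux[n + 1, AUX_O] = o_trpm4
        aux[n + 1, AUX_ITRPM4] = i_trpm4_pa
        aux[n + 1, AUX_ICLAMP] = i_clamp
        if status != OK:
            break

    return v_out, aux, status, status_comp
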