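"""Compiled backward-Euler core of the cable integrator.

One numba kernel advances the full compartment chain: gates are advanced by
an exact exponential update at frozen voltage (table-driven ``x_inf`` and
``1-exp(-dt/tau)`` factors), then the voltage vector is solved implicitly
with the Thomas algorithm on the tridiagonal cable system, then submembrane
calcium and the parvalbumin buffer are stepped by backward Euler.  All
quantities follow the convention: V in mV, t in ms, conductance densities in
S/cm2, current densities in mA/cm2, areas in cm2, concentrations in mM,
injected current in pA.
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1

_FARADAY = 96485.332
_V_LIMIT = 200.0  # |V| beyond this (mV) is numerical divergence


@njit(cache=True)
def _interp(tab, gi, idx, frac):
    return tab[gi, idx] + (tab[gi, idx + 1] - tab[gi, idx]) * frac


@njit(cache=True)
def step_loop(
    # mutable state
    v,            # (n,) membrane potential mV
    gh,           # (nh, ng) hillock gate states
    gn,           # (nnode, 3) nodal HH gate states (m, h, n)
    ca,           # (nh,) free submembrane calcium mM
    cab,          # (nh,) calcium-bound parvalbumin mM
    # protocol
    stim,         # (nsteps,) injected current at the soma, pA
    rec,          # (nsteps,) out: somatic V after each step
    dt,
    # geometry / passive
    cdt,          # (n,) 1e-3*cm*area/dt  [mA/mV]
    area,         # (n,) cm2
    gax,          # (n-1,) axial coupling conductance S between i and i+1
    gpas,         # (n,) passive leak conductance density S/cm2
    gepas,        # (n,) gpas*e_leak
    soma_idx,
    hil0,         # first hillock compartment
    nh,           # number of hillock compartments
    node_idx,     # (nnode,) compartment index of each node of Ranvier
    # free parameters: hillock channel maximal conductances (8,)
    gch,
    # packed hillock channel tables
    erev_ch, is_ca_ch,
    gate_ch, gate_exp, gate_kind,
    inf_tab, qfac_tab, vmin_tab, inv_dv, nv,
    ca_kd, ca_hill, ca_qfac,
    bk_vhalf, bk_slope, bk_shift, bk_lg_caref,
    # nodal HH
    g_na_node, g_k_node, g_l_node, e_na_node, e_k_node, e_l_node,
    inf_node, qfac_node,
    # calcium / buffer parameters
    ca_depth_um, ca_base, ca_tau, pv_total, pv_kon, pv_koff,
):
    n = v.shape[0]
    nsteps = stim.shape[0]
    ng = gate_ch.shape[0]
    nc = gch.shape[0]
    nnode = node_idx.shape[0]

    lo = np.empty(n)
    di = np.empty(n)
    up = np.empty(n)
    rhs = np.empty(n)
    cprime = np.empty(n)
    dprime = np.empty(n)
    prod = np.empty(nc)
    gca_g = np.empty(nh)   # summed calcium-channel conductance density per hillock comp
    gca_ge = np.empty(nh)  # same, weighted by reversal

    imax = nv - 2
    ext = dt / ca_tau

    for t in range(nsteps):
        # ---- membrane conductances ------------------------------------
        # passive part everywhere
        for i in range(n):
            di[i] = cdt[i] + area[i] * gpas[i]
            rhs[i] = cdt[i] * v[i] + area[i] * gepas[i]

        # hillock: advance gates at frozen V, accumulate channel conductances
        for j in range(nh):
            i = hil0 + j
            vv = v[i]
            x = (vv - vmin_tab) * inv_dv
            idx = int(x)
            if idx < 0:
                idx = 0
            elif idx > imax:
                idx = imax
            frac = x - idx
            caj = ca[j]
            for c in range(nc):
                prod[c] = 1.0
            for g in range(ng):
                k = gate_kind[g]
                if k == 0:  # voltage gate
                    inf = _interp(inf_tab, g, idx, frac)
                    q = _interp(qfac_tab, g, idx, frac)
                elif k == 1:  # calcium gate (SK)
                    r = (caj / ca_kd[g]) ** ca_hill[g]
                    inf = r / (1.0 + r)
                    q = ca_qfac[g]
                else:  # calcium-shifted voltage gate (BK)
                    vh = bk_vhalf[g] - bk_shift[g] * (math.log10(caj + 1e-12) - bk_lg_caref[g])
                    inf = 1.0 / (1.0 + math.exp(-(vv - vh) / bk_slope[g]))
                    q = _interp(qfac_tab, g, idx, frac)
                xg = gh[j, g] + (inf - gh[j, g]) * q
                gh[j, g] = xg
                p = gate_exp[g]
                xp = xg
                for _ in range(p - 1):
                    xp *= xg
                prod[gate_ch[g]] *= xp
            gsum = 0.0
            gesum = 0.0
            gca = 0.0
            gcae = 0.0
            for c in range(nc):
                gc = gch[c] * prod[c]
                gsum += gc
                gesum += gc * erev_ch[c]
                if is_ca_ch[c] == 1:
                    gca += gc
                    gcae += gc * erev_ch[c]
            gca_g[j] = gca
            gca_ge[j] = gcae
            di[i] += area[i] * gsum
            rhs[i] += area[i] * gesum

        # nodes of Ranvier: squid-type HH
        for k in range(nnode):
            i = node_idx[k]
            vv = v[i]
            x = (vv - vmin_tab) * inv_dv
            idx = int(x)
            if idx < 0:
                idx = 0
            elif idx > imax:
                idx = imax
            frac = x - idx
            for g in range(3):
                inf = _interp(inf_node, g, idx, frac)
                q = _interp(qfac_node, g, idx, frac)
                gn[k, g] = gn[k, g] + (inf - gn[k, g]) * q
            m = gn[k, 0]
            h = gn[k, 1]
            nn = gn[k, 2]
            gna = g_na_node * m * m * m * h
            gk = g_k_node * nn * nn * nn * nn
            gtot = gna + gk + g_l_node
            getot = gna * e_na_node + gk * e_k_node + g_l_node * e_l_node
            di[i] += area[i] * gtot
            rhs[i] += area[i] * getot

        # ---- implicit voltage solve (Thomas) ---------------------------
        rhs[soma_idx] += stim[t] * 1e-9  # pA -> mA
        for i in range(n):
            lo[i] = 0.0
            up[i] = 0.0
        for i in range(n - 1):
            g = gax[i]
            di[i] += g
            di[i + 1] += g
            up[i] = -g
            lo[i + 1] = -g

        cprime[0] = up[0] / di[0]
        dprime[0] = rhs[0] / di[0]
        for i in range(1, n):
            m_ = di[i] - lo[i] * cprime[i - 1]
            cprime[i] = up[i] / m_
            dprime[i] = (rhs[i] - lo[i] * dprime[i - 1]) / m_
        v[n - 1] = dprime[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = dprime[i] - cprime[i] * v[i + 1]

        # ---- calcium shell + parvalbumin exchange ----------------------
        for j in range(nh):
            i = hil0 + j
            ica = gca_g[j] * v[i] - gca_ge[j]  # mA/cm2, inward negative
            flux = -1e4 * ica / (2.0 * _FARADAY * ca_depth_um)  # mM/ms
            c0 = (ca[j] + dt * flux + ext * ca_base) / (1.0 + ext)
            if c0 < 0.0:
                c0 = 0.0
            if pv_total > 0.0:
                k1 = dt * pv_kon
                k2 = dt * pv_koff
                s = c0 + cab[j]
                beta = 1.0 + k2 + k1 * (pv_total - s)
                gamma = s * (1.0 + k2) - cab[j]
                c1 = (math.sqrt(beta * beta + 4.0 * k1 * gamma) - beta) / (2.0 * k1)
                cab[j] = s - c1
                c0 = c1
            ca[j] = c0

        rec[t] = v[soma_idx]

        # ---- divergence guard ------------------------------------------
        bad = False
        for i in range(n):
            if not math.isfinite(v[i]) or abs(v[i]) > _V_LIMIT:
                bad = True
                break
        if bad:
            for tt in range(t, nsteps):
                rec[tt] = v[soma_idx]
            return STATUS_DIVERGED

    return STATUS_OK
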