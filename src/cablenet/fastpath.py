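"""Compiled ensemble runner for primary-synapse (alpha input) studies.

The synapse-loss protocol runs hundreds of single-cell simulations that
differ only in their synapse sets.  This module executes such an ensemble
in one fused, JIT-compiled loop: shared tree-structured factorization per
step-size level, Hodgkin-Huxley gates, calcium machinery and
alpha-function synaptic inputs, with the same mixed implicit/explicit
scheme and CFL estimate as :mod:`cablenet.solver`.  It is an execution
backend, not a second model: a test pins its trajectories to the
reference solver.

Only primary synapses are supported here (the loss study has no
interconnecting synapses); anything else goes through the general solver.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .membrane import (FARADAY, GAS_CONSTANT, BODY_TEMPERATURE,
                       hh_steady_state, vdcc_gate_steady_state)
from .solver import CableSimulation, SimulationConfig

__all__ = ["run_alpha_ensemble"]

MAX_LEVELS = 48


@njit(cache=True)
def _factorize(level, have_factor, fac_diag, fac_mult, C, G, parent, dt):
    """Eliminate the one-superdiagonal tree matrix (C/dt + L) in place."""
    n = C.shape[0]
    d = fac_diag[level]
    m = fac_mult[level]
    for i in range(n):
        d[i] = C[i] / dt
    for i in range(n):
        if parent[i] >= 0:
            d[i] += G[i]
            d[parent[i]] += G[i]
    for i in range(n):
        p = parent[i]
        if p >= 0:
            m[i] = G[i] / d[i]  # multiplier for the elimination
            d[p] -= G[i] * m[i]
    have_factor[level] = True


@njit(cache=True)
def _run(parent, G, GD, C, area, vol,
         gK, gNa, gl, El, E_K, E_Na, c_T, V_rest,
         syn_vtx, syn_col, syn_g, syn_onset, syn_tau,
         ca_on, ca_mask,
         m_vhalf, m_z, m_gamma, m_K, m_taumin,
         h_vhalf, h_z, h_gamma, h_K, h_taumin,
         perm_ca, ncx_v, ncx_K, pmca_v, pmca_K, ca_leak, ca_out, ca_rest,
         ampa_frac,
         duration, dt_max, safety, record_interval,
         probes, V0, n_rec_cap):
    n = C.shape[0]
    k = V0.shape[1]
    V = V0.copy()
    n0, m0, h0 = 0.0, 0.0, 0.0  # filled below

    # gate initialisation at rest (classical rates at v = 0)
    an0 = 0.01 * 10.0 / (np.exp(1.0) - 1.0)
    bn0 = 0.125
    am0 = 0.1 * 25.0 / (np.exp(2.5) - 1.0)
    bm0 = 4.0
    ah0 = 0.07
    bh0 = 1.0 / (np.exp(3.0) + 1.0)
    n0 = an0 / (an0 + bn0)
    m0 = am0 / (am0 + bm0)
    h0 = ah0 / (ah0 + bh0)
    gate_n = np.full((n, k), n0)
    gate_m = np.full((n, k), m0)
    gate_h = np.full((n, k), h0)

    ca = np.full((n, k), ca_rest)
    FRT = FARADAY_C / (R_GAS * T_BODY)
    # VDCC gates at rest
    xm = m_z * (V_rest - m_vhalf) * FRT
    am = m_K * np.exp(m_gamma * xm)
    bm = m_K * np.exp(-(1.0 - m_gamma) * xm)
    vm0 = am / (am + bm)
    xh = h_z * (V_rest - h_vhalf) * FRT
    ah = h_K * np.exp(h_gamma * xh)
    bh = h_K * np.exp(-(1.0 - h_gamma) * xh)
    vh0 = ah / (ah + bh)
    vd_m = np.full((n, k), vm0)
    vd_h = np.full((n, k), vh0)

    have_factor = np.zeros(MAX_LEVELS, dtype=np.bool_)
    fac_diag = np.zeros((MAX_LEVELS, n))
    fac_mult = np.zeros((MAX_LEVELS, n))
    have_factor_ca = np.zeros(MAX_LEVELS, dtype=np.bool_)
    fac_diag_ca = np.zeros((MAX_LEVELS, n))
    fac_mult_ca = np.zeros((MAX_LEVELS, n))

    n_probe = probes.shape[0]
    rec_t = np.zeros(n_rec_cap)
    rec_V = np.zeros((n_rec_cap, n_probe, k))
    rec_ca = np.zeros((n_rec_cap, n_probe, k))
    rec_t[0] = 0.0
    for pi in range(n_probe):
        for b in range(k):
            rec_V[0, pi, b] = V[probes[pi], b]
            rec_ca[0, pi, b] = ca[probes[pi], b]
    n_rec = 1
    next_rec = record_interval

    # working arrays
    rhs = np.zeros((n, k))
    g_syn = np.zeros((n, k))
    i_syn = np.zeros((n, k))
    vdcc_flux = np.zeros((n, k))  # mol m⁻² s⁻¹ at the pre-step potential
    cond_max = np.zeros(n)  # worst-case membrane conductance per vertex

    # initial conductance (rest)
    for i in range(n):
        gk_open = gK[i] * n0 ** 4
        gna_open = gNa[i] * m0 ** 3 * h0
        cond_max[i] = c_T * (gk_open + gna_open + gl[i])

    t = 0.0
    Vr_mV = V_rest * 1e3
    status = 0
    while t < duration - 1e-15:
        # --- CFL estimate from current conductances + synapses (dyadic)
        dt = dt_max
        for i in range(n):
            bound = safety * C[i] / (cond_max[i] * area[i] + 1e-300)
            if bound < dt:
                dt = bound
        # include synaptic conductance from the previous evaluation
        for i in range(n):
            gmax_s = 0.0
            for b in range(k):
                if g_syn[i, b] > gmax_s:
                    gmax_s = g_syn[i, b]
            if gmax_s > 0.0:
                bound = safety * C[i] / (cond_max[i] * area[i] + gmax_s)
                if bound < dt:
                    dt = bound
        level = 0
        if dt < dt_max:
            level = int(np.ceil(np.log2(dt_max / dt)))
            if level >= MAX_LEVELS:
                status = 2
                break
            dt = dt_max / 2.0 ** level
        if t + dt > duration:
            pass  # keep the quantized dt; recording tolerates overshoot
        if not have_factor[level]:
            _factorize(level, have_factor, fac_diag, fac_mult, C, G,
                       parent, dt)
        if ca_on and not have_factor_ca[level]:
            _factorize(level, have_factor_ca, fac_diag_ca, fac_mult_ca,
                       vol, GD, parent, dt)

        # --- synaptic conductances and currents at time t
        for i in range(n):
            for b in range(k):
                g_syn[i, b] = 0.0
                i_syn[i, b] = 0.0
        for s in range(syn_vtx.shape[0]):
            dt_on = t - syn_onset[s]
            tau = syn_tau[s]
            if 0.0 <= dt_on <= 6.0 * tau:
                g = syn_g[s] * (dt_on / tau) * np.exp(-(dt_on - tau) / tau)
                vv = V[syn_vtx[s], syn_col[s]]
                g_syn[syn_vtx[s], syn_col[s]] += g
                i_syn[syn_vtx[s], syn_col[s]] += g * vv  # E_rev = 0

        # --- gate updates (explicit, pre-step V), then membrane
        # currents with the updated gates — the reference solver's order
        f_gate = c_T * dt * 1e3
        for i in range(n):
            cmax_i = 0.0
            for b in range(k):
                v = V[i, b]
                vm = v * 1e3 - Vr_mV
                x = 10.0 - vm
                if abs(x) < 1e-6:
                    a_n = 0.01 * (10.0 - x / 2.0)
                else:
                    a_n = 0.01 * x / (np.exp(x / 10.0) - 1.0)
                b_n = 0.125 * np.exp(-vm / 80.0)
                x = 25.0 - vm
                if abs(x) < 1e-6:
                    a_m = 0.1 * (10.0 - x / 2.0)
                else:
                    a_m = 0.1 * x / (np.exp(x / 10.0) - 1.0)
                b_m = 4.0 * np.exp(-vm / 18.0)
                a_h = 0.07 * np.exp(-vm / 20.0)
                b_h = 1.0 / (np.exp((30.0 - vm) / 10.0) + 1.0)
                nn = gate_n[i, b] + f_gate * (a_n - (a_n + b_n) * gate_n[i, b])
                mm = gate_m[i, b] + f_gate * (a_m - (a_m + b_m) * gate_m[i, b])
                hh = gate_h[i, b] + f_gate * (a_h - (a_h + b_h) * gate_h[i, b])
                nn = min(max(nn, 0.0), 1.0)
                mm = min(max(mm, 0.0), 1.0)
                hh = min(max(hh, 0.0), 1.0)
                gate_n[i, b] = nn
                gate_m[i, b] = mm
                gate_h[i, b] = hh

                if ca_on and ca_mask[i]:
                    xm = m_z * (v - m_vhalf) * FRT
                    am = m_K * np.exp(m_gamma * xm)
                    bm = m_K * np.exp(-(1.0 - m_gamma) * xm)
                    tau_m = 1.0 / (am + bm)
                    if tau_m < m_taumin:
                        tau_m = m_taumin
                    vd_m[i, b] += dt * (am / (am + bm) - vd_m[i, b]) / tau_m
                    if vd_m[i, b] < 0.0:
                        vd_m[i, b] = 0.0
                    elif vd_m[i, b] > 1.0:
                        vd_m[i, b] = 1.0
                    xh = h_z * (v - h_vhalf) * FRT
                    ah = h_K * np.exp(h_gamma * xh)
                    bh = h_K * np.exp(-(1.0 - h_gamma) * xh)
                    tau_h = 1.0 / (ah + bh)
                    if tau_h < h_taumin:
                        tau_h = h_taumin
                    vd_h[i, b] += dt * (ah / (ah + bh) - vd_h[i, b]) / tau_h
                    if vd_h[i, b] < 0.0:
                        vd_h[i, b] = 0.0
                    elif vd_h[i, b] > 1.0:
                        vd_h[i, b] = 1.0

                gk_open = gK[i] * nn * nn * nn * nn
                gna_open = gNa[i] * mm * mm * mm * hh
                i_m = c_T * (gk_open * (v - E_K) + gna_open * (v - E_Na)
                             + gl[i] * (v - El[i]))
                cnd = c_T * (gk_open + gna_open + gl[i])
                if cnd > cmax_i:
                    cmax_i = cnd
                I_total = area[i] * i_m + i_syn[i, b]
                if ca_on and ca_mask[i]:
                    xi = 2.0 * FRT * v
                    if abs(xi) < 1e-9:
                        frac = ca[i, b] - ca_out
                    else:
                        emx = np.exp(-xi)
                        frac = (ca[i, b] - ca_out * emx) / (1.0 - emx) * xi
                    po = vd_m[i, b] * vd_m[i, b] * vd_h[i, b]
                    vdcc_flux[i, b] = po * perm_ca * frac
                    I_total += area[i] * vdcc_flux[i, b] * 2.0 * FARADAY_C
                rhs[i, b] = C[i] / dt * v - I_total
            cond_max[i] = cmax_i

        # --- implicit tree solve per batch column (shared factorization)
        d = fac_diag[level]
        mlt = fac_mult[level]
        for b in range(k):
            for i in range(n):
                p = parent[i]
                if p >= 0:
                    rhs[p, b] += mlt[i] * rhs[i, b]
            for i in range(n - 1, -1, -1):
                p = parent[i]
                if p < 0:
                    V[i, b] = rhs[i, b] / d[i]
                else:
                    V[i, b] = (rhs[i, b] + G[i] * V[p, b]) / d[i]

        # divergence detection
        for i in range(n):
            for b in range(k):
                if not np.isfinite(V[i, b]) or abs(V[i, b]) > 1.0:
                    status = 1
                    break

        # --- calcium species step
        if ca_on:
            dca = fac_diag_ca[level]
            mca = fac_mult_ca[level]
            for b in range(k):
                for i in range(n):
                    flux = 0.0
                    if ca_mask[i]:
                        c = ca[i, b]
                        flux = (ncx_v * c / (ncx_K + c)
                                + pmca_v * c * c / (pmca_K * pmca_K + c * c)
                                + ca_leak + vdcc_flux[i, b])
                    inward = 0.0
                    if i_syn[i, b] < 0.0:
                        inward = ampa_frac * (-i_syn[i, b]) / (2.0 * FARADAY_C)
                    rhs[i, b] = (vol[i] / dt * ca[i, b]
                                 - area[i] * flux + inward)
                for i in range(n):
                    p = parent[i]
                    if p >= 0:
                        rhs[p, b] += mca[i] * rhs[i, b]
                for i in range(n - 1, -1, -1):
                    p = parent[i]
                    if p < 0:
                        ca[i, b] = rhs[i, b] / dca[i]
                    else:
                        ca[i, b] = (rhs[i, b] + GD[i] * ca[p, b]) / dca[i]
                for i in range(n):
                    if ca[i, b] < 0.0:
                        ca[i, b] = 0.0

        t += dt
        if status != 0:
            break
        if t >= next_rec - 1e-15 and n_rec < n_rec_cap:
            rec_t[n_rec] = t
            for pi in range(n_probe):
                for b in range(k):
                    rec_V[n_rec, pi, b] = V[probes[pi], b]
                    rec_ca[n_rec, pi, b] = ca[probes[pi], b]
            n_rec += 1
            while next_rec <= t:
                next_rec += record_interval

    return status, n_rec, rec_t, rec_V, rec_ca


# constants promoted to module level so numba can close over them
FARADAY_C = FARADAY
R_GAS = GAS_CONSTANT
T_BODY = BODY_TEMPERATURE


def run_alpha_ensemble(config: SimulationConfig):
    """Run an ensemble of primary-synapse simulations in the fused loop.

    Accepts the same configuration as :func:`cablenet.solver.simulate`
    restricted to primary synapses and no stimuli; returns
    ``(times, V, ca)`` with shapes (T,), (T, n_probes, k), where ``ca``
    is None when calcium is disabled.
    """
    if config.stimuli:
        raise ValueError("the fused ensemble runner takes no stimuli")
    sim = CableSimulation(config)  # reuse mesh/ordering/synapse binding
    if sim.handler.n_interconnecting:
        raise ValueError("only primary synapses supported in the fused loop")
    mesh, perm = sim.mesh, sim.perm
    n = mesh.n_vertices
    pos = np.empty(n, dtype=np.int64)
    pos[perm] = np.arange(n)

    parent = np.full(n, -1, dtype=np.int64)
    G = np.zeros(n)
    GD = np.zeros(n)
    D = config.calcium.diffusion if config.calcium is not None else 0.0
    for (a, b), g, L in zip(mesh.edges, mesh.G, mesh.edge_length):
        ia, ib = pos[a], pos[b]
        i, j = (ia, ib) if ia < ib else (ib, ia)
        parent[i] = j
        G[i] = g
        if config.calcium is not None:
            ra, rb = mesh.radius[a], mesh.radius[b]
            GD[i] = 2.0 * np.pi * D / ((ra ** -2 + rb ** -2) * L)

    spec = config.spec
    memb = sim.membrane
    k = sim.k

    def permute(arr):
        a = np.asarray(arr, dtype=float)
        a = a if a.ndim == 1 else a[:, 0]
        return a[perm]

    gK, gNa, gl, El = (permute(memb.g_K), permute(memb.g_Na),
                       permute(memb.g_l), permute(memb.E_l))
    C, area, vol = (mesh.capacitance[perm], mesh.area[perm],
                    mesh.volume[perm])

    h = sim.handler
    syn_vtx = pos[h.p_vtx]
    syn_col = h.p_col.astype(np.int64)
    syn_g = h.p_g
    syn_onset = h.p_onset
    syn_tau = h.p_tau

    ca_on = config.calcium is not None
    if ca_on:
        cp = config.calcium
        ca_mask = np.zeros(n, dtype=np.bool_)
        ca_mask[pos[sim.calcium.mask_idx]] = True
        vd = cp.vdcc
        ca_args = (vd.m_vhalf, vd.m_z, vd.m_gamma, vd.m_K, vd.m_tau_min,
                   vd.h_vhalf, vd.h_z, vd.h_gamma, vd.h_K, vd.h_tau_min,
                   vd.permeability, cp.pumps.ncx_vmax, cp.pumps.ncx_K,
                   cp.pumps.pmca_vmax, cp.pumps.pmca_K,
                   float(sim.calcium.leak_flux), vd.ca_external, cp.ca_rest,
                   cp.ampa_ca_fraction)
    else:
        ca_mask = np.zeros(n, dtype=np.bool_)
        ca_args = (0.0, 1.0, 0.5, 1.0, 1e-3, 0.0, 1.0, 0.5, 1.0, 1e-3,
                   0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 2.0, 5e-5, 0.0)

    probes = (np.asarray(config.probes, dtype=np.int64)
              if config.probes is not None else mesh.soma_vertices)
    probes_pos = pos[probes]
    V0 = np.full((n, k), spec.V_rest if config.V_init is None
                 else config.V_init)
    n_rec_cap = int(np.ceil(config.duration / config.record_interval)) + 2

    status, n_rec, rec_t, rec_V, rec_ca = _run(
        parent, G, GD, C, area, vol, gK, gNa, gl, El,
        spec.E_K, spec.E_Na, spec.c_T, spec.V_rest,
        syn_vtx, syn_col, syn_g, syn_onset, syn_tau,
        ca_on, ca_mask, *ca_args,
        config.duration, config.dt_max, config.safety,
        config.record_interval, probes_pos, V0, n_rec_cap)
    if status == 1:
        from .solver import SimulationDiverged
        raise SimulationDiverged(
            "membrane potential diverged in the fused ensemble loop; the "
            "step size exceeded the CFL bound")
    if status == 2:
        from .solver import SimulationDiverged
        raise SimulationDiverged("CFL estimate collapsed below the "
                                 "smallest supported dyadic step level")
    times = rec_t[:n_rec]
    V = rec_V[:n_rec]
    ca = rec_ca[:n_rec] if ca_on else None
    return times, V, ca
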