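"""Numba-compiled time-stepping kernel for network simulation.

One call advances the whole network state by ``n_steps`` of size ``dt``
(default 6400 steps = 200 ms, the connectivity-update cadence).  Neuron ODEs
use Strang splitting: a half-step exact exponential relaxation of all gating
variables at frozen voltage/calcium, a full explicit-midpoint step of the
voltage and calcium pools at frozen gates, then a second gating half-step.
Synaptic gating, efficacies (Euler-Maruyama) and the structural low-pass
calcium are advanced by forward Euler at the same dt.

All model equations are duplicated here from the reference implementations in
:mod:`stngpe.neurons`, :mod:`stngpe.synapses` and :mod:`stngpe.plasticity`;
the test suite asserts single-step parity between the two paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# gate indices
G_M, G_H, G_N, G_P, G_Q, G_A, G_B, G_C, G_D1, G_D2, G_R = range(11)
# channel conductance indices in gcond
C_NA, C_K, C_T, C_CAK, C_A, C_L, C_LEAK = range(7)
# transmitter rows in tp
T_GABA, T_AMPA, T_NMDA = 0, 1, 2


@njit(cache=True, inline="always")
def _lerp(tab, p, g, u, ntab):
    if u < 0.0:
        u = 0.0
    elif u > ntab - 1.000001:
        u = ntab - 1.000001
    i0 = int(u)
    w = u - i0
    return tab[p, g, i0] * (1.0 - w) + tab[p, g, i0 + 1] * w


@njit(cache=True, inline="always")
def _lerp1(tab, u, ntab):
    if u < 0.0:
        u = 0.0
    elif u > ntab - 1.000001:
        u = ntab - 1.000001
    i0 = int(u)
    w = u - i0
    return tab[i0] * (1.0 - w) + tab[i0 + 1] * w


@njit(cache=True, fastmath=True, inline="always")
def _relax_gates(i, p, V_i, ca_i, gates, guse, gisca,
                 xinf_tab, relax_tab, m0, inv_dm, ntab):
    """Exact exponential relaxation of neuron i's gates over one half step.

    Steady states and relaxation factors exp(-dt/2 tau) are linearly
    interpolated from tables precomputed with the reference gate kinetics.
    """
    for g in range(11):
        if guse[p, g] == 0:
            continue
        M = ca_i if gisca[g] == 1 else V_i
        u = (M - m0[g]) * inv_dm[g]
        xinf = _lerp(xinf_tab, p, g, u, ntab)
        fac = _lerp(relax_tab, p, g, u, ntab)
        gates[i, g] = xinf + (gates[i, g] - xinf) * fac


@njit(cache=True, fastmath=True)
def run_block(step0, n_steps, dt,
              # neuron state
              pop, V, gates, ca_soma, ca_seg, ca_L, bias, inj, last_spike,
              # neuron parameters (tabulated gate kinetics)
              guse, gisca, xinf_tab, relax_tab, m0, inv_dm, ntab,
              mgs_tab, mgc_tab, v0_tab, inv_dv_tab,
              gcond, Cm, E_Na, E_K, E_leak, ca_out, nernst_scale,
              ca_floor, k_ca, k_conv, v_thresh, refrac_steps,
              # synapse state
              sy_post, sy_seg, sy_exc, sy_plastic, sy_pop, rho, s, fpre_until,
              sy_wmin, sy_wmax, on_ampa, on_nmda, on_gaba,
              tp, E_gaba, E_ampa, E_nsyn, E_nca, f_nsyn, f_nca,
              # adjacency (CSR)
              out_ptr, out_syn, ctx_ptr, ctx_syn, msn_ptr, msn_syn,
              # afferent events for this block (absolute steps, sorted)
              ctx_ev_step, ctx_ev_gen, msn_ev_step, msn_ev_gen,
              # plasticity
              plast_on, tau_rho, gamma_p, gamma_d, sigma_n,
              theta_d, theta_p, noise_seed,
              # structural low-pass
              tau_ca_l,
              # spike output buffers
              sp_n, sp_step,
              # probes
              stride, pv_idx, pv_buf, pca_n, pca_seg, pca_buf, pr_syn, pr_buf,
              # threshold-occupancy step counters, shape (n, 3) each
              occ_d, occ_p):
    np.random.seed(noise_seed)
    n = V.shape[0]
    m = sy_post.shape[0]
    agg_g = np.zeros(n)
    agg_ge = np.zeros(n)
    agg_nsyn = np.zeros(n)
    agg_nca = np.zeros((n, 3))
    spiked = np.empty(n, dtype=np.int64)
    sp_count = 0
    ev_c = 0
    ev_m = 0
    n_ev_c = ctx_ev_step.shape[0]
    n_ev_m = msn_ev_step.shape[0]
    dt_half = 0.5 * dt
    noise_scale = sigma_n * np.sqrt(dt / tau_rho)
    # precomputed per-transmitter Euler coefficients:
    # decay factors 1 - dt/tau and drive terms dt*phi(, *nu)
    dec = np.empty((3, 3))
    drv_phi = np.empty(3)
    drv_f = np.empty(3)
    drv_s = np.empty(3)
    for y in range(3):
        dec[y, 0] = 1.0 - dt / tp[y, 3]
        dec[y, 1] = 1.0 - dt / tp[y, 4]
        dec[y, 2] = 1.0 - dt / tp[y, 5]
        drv_phi[y] = dt * tp[y, 0]
        drv_f[y] = dt * tp[y, 0] * tp[y, 1]
        drv_s[y] = dt * tp[y, 0] * tp[y, 2]

    for it in range(n_steps):
        gstep = step0 + it
        t = gstep * dt

        # -- afferent release events -------------------------------------
        while ev_c < n_ev_c and ctx_ev_step[ev_c] == gstep:
            gen = ctx_ev_gen[ev_c]
            for k in range(ctx_ptr[gen], ctx_ptr[gen + 1]):
                j = ctx_syn[k]
                e = t + 1.0
                if e > fpre_until[j]:
                    fpre_until[j] = e
            ev_c += 1
        while ev_m < n_ev_m and msn_ev_step[ev_m] == gstep:
            gen = msn_ev_gen[ev_m]
            for k in range(msn_ptr[gen], msn_ptr[gen + 1]):
                j = msn_syn[k]
                e = t + 1.0
                if e > fpre_until[j]:
                    fpre_until[j] = e
            ev_m += 1

        # -- synapse gating (forward Euler) + conductance aggregation -----
        for i in range(n):
            agg_g[i] = 0.0
            agg_ge[i] = 0.0
            agg_nsyn[i] = 0.0
            agg_nca[i, 0] = 0.0
            agg_nca[i, 1] = 0.0
            agg_nca[i, 2] = 0.0
        for j in range(m):
            f = 1.0 if t < fpre_until[j] else 0.0
            post = sy_post[j]
            g_fast = sy_wmin[j] + (sy_wmax[j] - sy_wmin[j]) * rho[j]
            if sy_exc[j] == 1:
                # AMPA components (cols 0..2), NMDA (cols 3..5)
                if f > 0.0:
                    s[j, 0] = s[j, 0] * dec[T_AMPA, 0] + drv_phi[T_AMPA] * (
                        1.0 - s[j, 1] - s[j, 2])
                    s[j, 1] = s[j, 1] * (dec[T_AMPA, 1] - drv_phi[T_AMPA]) + drv_f[T_AMPA]
                    s[j, 2] = s[j, 2] * (dec[T_AMPA, 2] - drv_phi[T_AMPA]) + drv_s[T_AMPA]
                    s[j, 3] = s[j, 3] * dec[T_NMDA, 0] + drv_phi[T_NMDA] * (
                        1.0 - s[j, 4] - s[j, 5])
                    s[j, 4] = s[j, 4] * (dec[T_NMDA, 1] - drv_phi[T_NMDA]) + drv_f[T_NMDA]
                    s[j, 5] = s[j, 5] * (dec[T_NMDA, 2] - drv_phi[T_NMDA]) + drv_s[T_NMDA]
                else:
                    s[j, 0] *= dec[T_AMPA, 0]
                    s[j, 1] *= dec[T_AMPA, 1]
                    s[j, 2] *= dec[T_AMPA, 2]
                    s[j, 3] *= dec[T_NMDA, 0]
                    s[j, 4] *= dec[T_NMDA, 1]
                    s[j, 5] *= dec[T_NMDA, 2]
                if on_ampa[j] == 1:
                    ga = g_fast * (s[j, 0] + s[j, 1] + s[j, 2])
                    agg_g[post] += ga
                    agg_ge[post] += ga * E_ampa
                if on_nmda[j] == 1:
                    gn = f_nsyn * g_fast * (s[j, 3] + s[j, 4] + s[j, 5])
                    agg_nsyn[post] += gn
                    agg_nca[post, sy_seg[j]] += f_nca * gn
            else:
                if f > 0.0:
                    s[j, 0] = s[j, 0] * dec[T_GABA, 0] + drv_phi[T_GABA] * (
                        1.0 - s[j, 1] - s[j, 2])
                    s[j, 1] = s[j, 1] * (dec[T_GABA, 1] - drv_phi[T_GABA]) + drv_f[T_GABA]
                    s[j, 2] = s[j, 2] * (dec[T_GABA, 2] - drv_phi[T_GABA]) + drv_s[T_GABA]
                else:
                    s[j, 0] *= dec[T_GABA, 0]
                    s[j, 1] *= dec[T_GABA, 1]
                    s[j, 2] *= dec[T_GABA, 2]
                if on_gaba[j] == 1:
                    gg = g_fast * (s[j, 0] + s[j, 1] + s[j, 2])
                    agg_g[post] += gg
                    agg_ge[post] += gg * E_gaba

        # -- neuron update: Strang splitting ------------------------------
        n_spiked = 0
        for i in range(n):
            p = pop[i]
            _relax_gates(i, p, V[i], ca_soma[i], gates, guse, gisca,
                         xinf_tab, relax_tab, m0, inv_dm, ntab)

            # frozen channel activations
            act_na = gates[i, G_M] ** 3 * gates[i, G_H]
            act_k = gates[i, G_N] ** 4
            act_t = gates[i, G_P] ** 2 * gates[i, G_Q]
            act_cak = gates[i, G_R] ** 2
            act_a = gates[i, G_A] ** 2 * gates[i, G_B]
            act_l = gates[i, G_C] ** 2 * gates[i, G_D1] * gates[i, G_D2]
            g_na = gcond[p, C_NA] * act_na
            g_k = gcond[p, C_K] * act_k
            g_t = gcond[p, C_T] * act_t
            g_cak = gcond[p, C_CAK] * act_cak
            g_a = gcond[p, C_A] * act_a
            g_l = gcond[p, C_L] * act_l
            g_leak = gcond[p, C_LEAK]

            v0 = V[i]
            cs0 = ca_soma[i]
            c0_0 = ca_seg[i, 0]
            c0_1 = ca_seg[i, 1]
            c0_2 = ca_seg[i, 2]

            vv = v0
            cs = cs0
            for stage in range(2):
                csf = cs if cs > ca_floor else ca_floor
                eca = nernst_scale * np.log(ca_out / csf)
                i_t = g_t * (vv - eca)
                i_l = g_l * (vv - eca)
                i_ion = (g_na * (vv - E_Na) + g_k * (vv - E_K) + i_t
                         + g_cak * (vv - E_K) + g_a * (vv - E_K) + i_l
                         + g_leak * (vv - E_leak))
                uv = (vv - v0_tab) * inv_dv_tab
                m_syn = _lerp1(mgs_tab, uv, ntab)
                m_ca = _lerp1(mgc_tab, uv, ntab)
                i_nsyn = agg_nsyn[i] * m_syn * (vv - E_nsyn)
                inca0 = agg_nca[i, 0] * m_ca * (vv - E_nca)
                inca1 = agg_nca[i, 1] * m_ca * (vv - E_nca)
                inca2 = agg_nca[i, 2] * m_ca * (vv - E_nca)
                i_lin = agg_g[i] * vv - agg_ge[i]
                i_cav = i_t + i_l
                dv = (-i_ion + bias[i] + inj[i] - i_lin - i_nsyn
                      - inca0 - inca1 - inca2) / Cm[p]
                dcs = -k_conv * (i_cav + inca0 + inca1 + inca2) - k_ca * cs
                if stage == 0:
                    # midpoint predictor
                    vv = v0 + dt_half * dv
                    cs = cs0 + dt_half * dcs
                    dc0_h = -k_conv * (i_cav + inca0) - k_ca * c0_0
                    dc1_h = -k_conv * (i_cav + inca1) - k_ca * c0_1
                    dc2_h = -k_conv * (i_cav + inca2) - k_ca * c0_2
                    c_0 = c0_0 + dt_half * dc0_h
                    c_1 = c0_1 + dt_half * dc1_h
                    c_2 = c0_2 + dt_half * dc2_h
                else:
                    V[i] = v0 + dt * dv
                    cs_new = cs0 + dt * dcs
                    ca_soma[i] = cs_new if cs_new > 0.0 else 0.0
                    dc0 = -k_conv * (i_cav + inca0) - k_ca * c_0
                    dc1 = -k_conv * (i_cav + inca1) - k_ca * c_1
                    dc2 = -k_conv * (i_cav + inca2) - k_ca * c_2
                    x = c0_0 + dt * dc0
                    ca_seg[i, 0] = x if x > 0.0 else 0.0
                    x = c0_1 + dt * dc1
                    ca_seg[i, 1] = x if x > 0.0 else 0.0
                    x = c0_2 + dt * dc2
                    ca_seg[i, 2] = x if x > 0.0 else 0.0

            _relax_gates(i, p, V[i], ca_soma[i], gates, guse, gisca,
                         xinf_tab, relax_tab, m0, inv_dm, ntab)

            # spike detection: upward crossing of v_thresh with refractory
            if v0 < v_thresh and V[i] >= v_thresh:
                if gstep - last_spike[i] >= refrac_steps:
                    last_spike[i] = gstep
                    spiked[n_spiked] = i
                    n_spiked += 1
                    if sp_count < sp_n.shape[0]:
                        sp_n[sp_count] = i
                        sp_step[sp_count] = gstep
                        sp_count += 1

        # -- propagate spikes to outgoing synapses (next step onward) -----
        t_next = (gstep + 1) * dt
        for k in range(n_spiked):
            i = spiked[k]
            for q in range(out_ptr[i], out_ptr[i + 1]):
                j = out_syn[q]
                e = t_next + 1.0
                if e > fpre_until[j]:
                    fpre_until[j] = e

        # -- synaptic plasticity (Euler-Maruyama on rho) -------------------
        if plast_on == 1:
            for j in range(m):
                if sy_plastic[j] == 0:
                    continue
                ca = ca_seg[sy_post[j], sy_seg[j]]
                pp = sy_pop[j]
                r0 = rho[j]
                drift = -r0 * (1.0 - r0) * (0.5 - r0)
                if ca >= theta_d[pp]:
                    drift -= gamma_d * r0
                    if ca >= theta_p[pp]:
                        drift += gamma_p * (1.0 - r0)
                    r1 = r0 + dt * drift / tau_rho
                    if sigma_n > 0.0:
                        r1 += noise_scale * np.random.standard_normal()
                else:
                    r1 = r0 + dt * drift / tau_rho
                if r1 < 0.0:
                    r1 = 0.0
                elif r1 > 1.0:
                    r1 = 1.0
                rho[j] = r1

        # -- low-pass calcium for structural plasticity --------------------
        for i in range(n):
            ca_L[i] += dt * (ca_soma[i] - ca_L[i]) / tau_ca_l
            pp = pop[i]
            for l in range(3):
                if ca_seg[i, l] >= theta_d[pp]:
                    occ_d[i, l] += 1
                    if ca_seg[i, l] >= theta_p[pp]:
                        occ_p[i, l] += 1

        # -- probes --------------------------------------------------------
        if it % stride == 0:
            rec = it // stride
            for k in range(pv_idx.shape[0]):
                pv_buf[k, rec] = V[pv_idx[k]]
            for k in range(pca_n.shape[0]):
                if pca_seg[k] < 0:
                    pca_buf[k, rec] = ca_soma[pca_n[k]]
                else:
                    pca_buf[k, rec] = ca_seg[pca_n[k], pca_seg[k]]
            for k in range(pr_syn.shape[0]):
                pr_buf[k, rec] = rho[pr_syn[k]]

    return sp_count
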