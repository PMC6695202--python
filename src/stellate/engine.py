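"""Compiled core of the branched-cable Hodgkin-Huxley integrator.

One numba kernel advances the whole model: Rush-Larsen gating updates from
pre-tabulated rate functions, bi-exponential synaptic conductance states driven
by a sorted event list, an implicit (Crank-Nicolson via extrapolated backward
Euler) tree solve in Hines order, somatic conductance-clamp injection, calcium
bookkeeping, on-line spike detection and per-class charge accounting.

Units throughout: mV, ms, uS, nA, nF, um, mM.  Inward membrane current is
negative.  Compartments are ordered root-first so ``parent[i] < i``.

Charge accumulators and recorded current traces are evaluated at the
pre-solve voltage of each step (one half step behind the solved voltage),
which at the default time steps is indistinguishable from mid-step quadrature.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F_COULOMB = 96485.332  # C/mol
CA_SHELL_DEPTH = 0.1  # um, submembrane shell for the calcium pool
CA_REST = 1e-4  # mM (100 nM)
CA_OUT = 2.0  # mM


@njit(cache=True, fastmath=True)
def _interp(table, g, v, vmin, inv_dv, nv):
    x = (v - vmin) * inv_dv
    if x < 0.0:
        x = 0.0
    elif x > nv - 1.001:
        x = nv - 1.001
    i = int(x)
    f = x - i
    return table[g, i] * (1.0 - f) + table[g, i + 1] * f


@njit(cache=True, fastmath=True)
def run_model(
    # topology / passive
    parent, cap, g_leak, e_leak, g_ax,
    # active conductances (uS per compartment) and reversals (mV)
    g_na, g_kdr, g_ks, g_ca, e_na, e_k, e_ca,
    # gate tables
    tab_inf, tab_dec, vmin, inv_dv,
    # synapse classes: decay factors per step, reversals, peak-normalisation
    syn_dec_r, syn_dec_f, syn_e, syn_norm,
    # events (sorted by step)
    ev_step, ev_comp, ev_class, ev_w,
    # somatic conductance-clamp traces (n_inj x n_steps) with reversals
    inj_g, inj_e,
    # constant current injection per compartment (nA)
    i_const,
    # calcium system
    ca_on, ca_diff, ca_btot, ca_kon, ca_koff, ca_ptot, ca_k1, ca_k2, ca_k3, ca_k4,
    # integration control
    dt, n_steps, rec_every, record_traces,
    spike_thresh, lockout_steps,
    # geometry for the calcium shell (um, um^2)
    length, area,
):
    n = parent.shape[0]
    n_cls = syn_e.shape[0]
    n_inj = inj_e.shape[0]
    nv = tab_inf.shape[1]

    v = np.full(n, -70.0)
    m = np.empty(n)
    h = np.empty(n)
    ng = np.empty(n)
    p = np.empty(n)
    q = np.empty(n)
    for i in range(n):
        m[i] = _interp(tab_inf, 0, v[i], vmin, inv_dv, nv)
        h[i] = _interp(tab_inf, 1, v[i], vmin, inv_dv, nv)
        ng[i] = _interp(tab_inf, 2, v[i], vmin, inv_dv, nv)
        p[i] = _interp(tab_inf, 3, v[i], vmin, inv_dv, nv)
        q[i] = _interp(tab_inf, 4, v[i], vmin, inv_dv, nv)

    # synapse states: rise (a) and fall (b) exponentials; b >= a >= 0 always
    sa = np.zeros((n, n_cls))
    sb = np.zeros((n, n_cls))

    # calcium pools
    ca = np.full(n, CA_REST)
    cabound = np.zeros(n)
    pumpca = np.zeros(n)
    if ca_on:
        for i in range(n):
            cabound[i] = ca_btot * ca[i] / (ca[i] + ca_koff / ca_kon)

    # recording buffers
    n_rec = (n_steps - 1) // rec_every + 1 if record_traces else 1
    vm_rec = np.zeros(n_rec)
    i_cls_rec = np.zeros((n_cls, n_rec))
    i_na_rec = np.zeros(n_rec)
    i_inj_rec = np.zeros((max(n_inj, 1), n_rec))
    vm_rec[0] = v[0]

    # charge accumulators (pC)
    q_cls = np.zeros(n_cls)
    q_na_tot = 0.0
    q_inj = np.zeros(max(n_inj, 1))

    max_spikes = n_steps // lockout_steps + 8
    spikes = np.zeros(max_spikes)
    n_spikes = 0
    last_cross = -10 * lockout_steps

    diag = np.empty(n)
    rhs = np.empty(n)
    vb = np.empty(n)
    i_cls_now = np.zeros(n_cls)

    # Crank-Nicolson = backward-Euler half step at dt/2, then extrapolation
    cap_dt = cap / (0.5 * dt)
    ca_in_scale = 1e7 / (2.0 * F_COULOMB * area)
    pump_scale = 1e6 / (CA_SHELL_DEPTH * 1e-4)
    diff_rate = np.zeros(n)
    for i in range(1, n):
        d_half = 0.5 * (length[i] + length[parent[i]])
        diff_rate[i] = ca_diff / (d_half * d_half)

    ev_ptr = 0
    m_ev = ev_step.shape[0]
    status = 0  # 0 ok, 1 diverged
    t_fail = -1.0

    for step in range(n_steps):
        rec_now = record_traces and step % rec_every == 0
        k_rec = step // rec_every

        # --- synaptic events landing in this step -------------------------
        while ev_ptr < m_ev and ev_step[ev_ptr] == step:
            c = ev_class[ev_ptr]
            i = ev_comp[ev_ptr]
            w = ev_w[ev_ptr] / syn_norm[c]
            sa[i, c] += w
            sb[i, c] += w
            ev_ptr += 1

        if rec_now:
            vm_rec[k_rec] = v[0]

        # --- gating update, synapse decay, currents and system assembly ---
        for c in range(n_cls):
            i_cls_now[c] = 0.0
        i_na_now = 0.0
        for i in range(n):
            vi = v[i]
            x = (vi - vmin) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > nv - 1.001:
                x = nv - 1.001
            ii = int(x)
            f = x - ii
            g1 = 1.0 - f
            mi = tab_inf[0, ii] * g1 + tab_inf[0, ii + 1] * f
            md = tab_dec[0, ii] * g1 + tab_dec[0, ii + 1] * f
            hi_ = tab_inf[1, ii] * g1 + tab_inf[1, ii + 1] * f
            hd = tab_dec[1, ii] * g1 + tab_dec[1, ii + 1] * f
            ni = tab_inf[2, ii] * g1 + tab_inf[2, ii + 1] * f
            nd = tab_dec[2, ii] * g1 + tab_dec[2, ii + 1] * f
            pi_ = tab_inf[3, ii] * g1 + tab_inf[3, ii + 1] * f
            pd_ = tab_dec[3, ii] * g1 + tab_dec[3, ii + 1] * f
            qi = tab_inf[4, ii] * g1 + tab_inf[4, ii + 1] * f
            qd = tab_dec[4, ii] * g1 + tab_dec[4, ii + 1] * f
            m[i] = mi + (m[i] - mi) * md
            h[i] = hi_ + (h[i] - hi_) * hd
            ng[i] = ni + (ng[i] - ni) * nd
            p[i] = pi_ + (p[i] - pi_) * pd_
            q[i] = qi + (q[i] - qi) * qd

            gna_i = g_na[i] * m[i] * m[i] * m[i] * h[i]
            n2 = ng[i] * ng[i]
            gk_i = g_kdr[i] * n2 * n2 + g_ks[i] * p[i]
            gca_i = g_ca[i] * q[i] * q[i]
            gtot = g_leak[i] + gna_i + gk_i + gca_i
            r = (
                g_leak[i] * e_leak[i]
                + gna_i * e_na
                + gk_i * e_k
                + gca_i * e_ca
                + i_const[i]
            )
            i_na_now += gna_i * (vi - e_na)
            for c in range(n_cls):
                b = sb[i, c]
                if b > 1e-14:
                    a = sa[i, c] * syn_dec_r[c]
                    b *= syn_dec_f[c]
                    sa[i, c] = a
                    sb[i, c] = b
                    gs = b - a
                    gtot += gs
                    r += gs * syn_e[c]
                    i_cls_now[c] += gs * (vi - syn_e[c])
            diag[i] = cap_dt[i] + gtot
            rhs[i] = cap_dt[i] * vi + r
        # axial coupling enters both diagonals
        for i in range(1, n):
            diag[i] += g_ax[i]
            diag[parent[i]] += g_ax[i]
        # somatic conductance clamp
        for j in range(n_inj):
            gj = inj_g[j, step]
            diag[0] += gj
            rhs[0] += gj * inj_e[j]
            iinj = gj * (v[0] - inj_e[j])
            if iinj < 0.0:
                q_inj[j] += -iinj * dt
            if rec_now:
                i_inj_rec[j, k_rec] = iinj

        # charge accounting (inward parts, rectangle rule at full dt)
        q_na_tot += -i_na_now * dt
        for c in range(n_cls):
            if i_cls_now[c] < 0.0:
                q_cls[c] += -i_cls_now[c] * dt
            if rec_now:
                i_cls_rec[c, k_rec] = i_cls_now[c]

        # --- Hines elimination / back-substitution ------------------------
        for i in range(n - 1, 0, -1):
            pa = parent[i]
            f = g_ax[i] / diag[i]
            diag[pa] -= g_ax[i] * f
            rhs[pa] += rhs[i] * f
        vprev_soma = v[0]
        vb[0] = rhs[0] / diag[0]
        v[0] = 2.0 * vb[0] - v[0]
        for i in range(1, n):
            # Crank-Nicolson: extrapolate the backward-Euler half step
            vbi = (rhs[i] + g_ax[i] * vb[parent[i]]) / diag[i]
            vb[i] = vbi
            v[i] = 2.0 * vbi - v[i]

        # --- calcium bookkeeping (no feedback on V beyond I_Ca) -----------
        if ca_on:
            for i in range(n):
                ica = g_ca[i] * q[i] * q[i] * (vb[i] - e_ca)
                dca = 0.0
                if ica < 0.0:
                    dca = -ica * ca_in_scale[i]
                bfree = ca_btot - cabound[i]
                jbuf = ca_kon * ca[i] * bfree - ca_koff * cabound[i]
                pfree = ca_ptot - pumpca[i]
                jon = ca_k1 * ca[i] * pfree - ca_k2 * pumpca[i]
                joff = ca_k3 * pumpca[i] - ca_k4 * CA_OUT * pfree
                pumpca[i] += dt * (jon - joff)
                if pumpca[i] < 0.0:
                    pumpca[i] = 0.0
                jpump = jon * pump_scale
                ca[i] += dt * (dca - jbuf - jpump)
                cabound[i] += dt * jbuf
                if ca[i] < 0.0:
                    ca[i] = 0.0
                if cabound[i] < 0.0:
                    cabound[i] = 0.0
            if ca_diff > 0.0:
                for i in range(1, n):
                    pa = parent[i]
                    flux = diff_rate[i] * (ca[pa] - ca[i]) * dt
                    ca[i] += flux
                    ca[pa] -= flux

        if rec_now:
            i_na_rec[k_rec] = i_na_now

        # --- spike detection on the somatic voltage -----------------------
        if vprev_soma < spike_thresh and v[0] >= spike_thresh:
            if step - last_cross >= lockout_steps and n_spikes < max_spikes:
                frac = (spike_thresh - vprev_soma) / (v[0] - vprev_soma)
                spikes[n_spikes] = (step + frac) * dt
                n_spikes += 1
                last_cross = step
        # --- divergence guard ---------------------------------------------
        if step % 512 == 0:
            if not np.isfinite(v[0]) or abs(v[0]) > 200.0:
                status = 1
                t_fail = step * dt
                break

    if status == 0 and (not np.isfinite(v[0]) or abs(v[0]) > 200.0):
        status = 1
        t_fail = n_steps * dt

    return (
        v, spikes[:n_spikes], q_cls, q_na_tot, q_inj,
        vm_rec, i_cls_rec, i_na_rec, i_inj_rec,
        status, t_fail,
    )
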