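"""Numba kernels: implicit mechanics solver and the spiking-network engine.

The biomechanical state is advanced by a fixed-step Runge-Kutta integrator
whose rate function solves the two pressure-balance equations (rib cage and
diaphragm) for the state rates by damped Newton iteration.  The network
engine advances every neuron with an exponential-Euler discretisation of
MacGregor-style integrate-and-fire dynamics and delivers spikes through a
delay ring buffer.  All functions here are internal; the public surface
lives in :mod:`coughsim.mechanics` and :mod:`coughsim.network`.
"""

import math

import numpy as np
from numba import njit

# Indices into the packed mechanics-constant vector (see mechanics.pack_mech).
MC_NAMES = [
    "C1", "V_c", "V_sum", "V_L0", "C_L",
    "sigma_di_max", "V_di_FRC", "K_dipsv", "R_di", "L_di_min",
    "V_di0", "Vdot_di_max", "V_ab0", "C_ab", "R_ab",
    "F_CEmax", "k", "L_CE0", "V_CEmax", "sigma_rc_mul",
    "sigma_rc_add", "V_rc_min", "V_rc_max", "R_rc", "V_di_TLC",
    "fa_TLC", "F_di", "P_icadi_TLC", "P_icaab_RV", "P_icaab_TLC",
    "V_rc_RV", "V_rc_TLC", "D", "d_min", "VC",
    "V_L_RV", "c_t",
]
MC_INDEX = {name: i for i, name in enumerate(MC_NAMES)}

RS_SLOPE = 8.00479
RS_INTERCEPT = -1.10158

# Glottal-diameter break point: above this net laryngeal activation the
# glottis is as wide as the trachea.
ULM_BREAK = 71.0 / 109.0


@njit(cache=True, fastmath=True)
def _safe_exp(x):
    if x > 50.0:
        x = 50.0
    elif x < -50.0:
        x = -50.0
    return math.exp(x)


@njit(cache=True, fastmath=True)
def glottal_diameter_mm(u_lm, D):
    """Equivalent glottal diameter (mm) from net laryngeal activation."""
    if u_lm > ULM_BREAK:
        return D
    if u_lm < -1.0:
        return 0.0
    return 10.9 * (1.0 + u_lm)


@njit(cache=True, fastmath=True)
def rohrer_k1(d):
    return 49.6 / d ** 4


@njit(cache=True, fastmath=True)
def rohrer_k2(d, D):
    """Orifice coefficient; vanishes as the glottis approaches tracheal bore."""
    beta = d / D
    return 0.167 * (1.0 / beta ** 4 - 1.0) * (1.0 - beta * beta)


@njit(cache=True, fastmath=True)
def hill_fv(ratio):
    """Hill force-velocity factor of shortening-rate ratio (shortening < 0)."""
    return 0.1433 / (0.1074 + _safe_exp(-1.409 * math.sinh(3.2 * ratio + 1.6)))


@njit(cache=True, fastmath=True)
def _geom_eval(v_ab, gv0, gdv, rt_tab, lce_tab, dld_tab, c_t):
    """Linear table lookup of r_t, r_s, L_CE, dL_CE/dV at abdominal volume."""
    n = rt_tab.shape[0]
    if v_ab <= 0.0:
        rt = 0.5 * c_t
        return rt, RS_SLOPE * rt + RS_INTERCEPT, 100.0 * rt * (math.pi / 2.0), 0.0
    x = (v_ab - gv0) / gdv
    if x <= 0.0:
        i = 0
        f = 0.0
    elif x >= n - 1.0:
        i = n - 2
        f = 1.0
    else:
        i = int(x)
        f = x - i
    rt = rt_tab[i] * (1.0 - f) + rt_tab[i + 1] * f
    lce = lce_tab[i] * (1.0 - f) + lce_tab[i + 1] * f
    dld = dld_tab[i] * (1.0 - f) + dld_tab[i + 1] * f
    return rt, RS_SLOPE * rt + RS_INTERCEPT, lce, dld


@njit(cache=True, fastmath=True)
def mech_residuals(x0, x1, closed, v_di, v_ab, u_di, u_ab, d,
                   mc, gv0, gdv, rt_tab, lce_tab, dld_tab):
    """Residuals of the rib-cage and diaphragm pressure balances.

    Open glottis: unknowns are the state rates (x0, x1) = (V'di, V'ab) and
    pleural pressure follows from airway resistance and lung recoil.  Closed
    glottis: lung volume is frozen (V'L = 0), the abdominal rate is slaved to
    the diaphragm rate, and (x0, x1) = (V'di, Ppl) with pleural pressure an
    unknown of the trapped-gas configuration.
    """
    c1 = mc[0]
    if closed:
        vdot_di = x0
        ppl = x1
        vdot_ab = -(1.0 + c1) * vdot_di
        vdot_l = 0.0
    else:
        vdot_di = x0
        vdot_ab = x1
        vdot_l = (-(1.0 + c1) * vdot_di - vdot_ab) / c1
        ppl = 0.0  # assigned below

    v_l = (mc[2] - (1.0 + c1) * v_di - v_ab - c1 * mc[1]) / c1
    v_rc = v_l + v_di + mc[1]
    vdot_rc = vdot_l + vdot_di

    sigma_l = (v_l - mc[3]) / mc[4]
    if not closed:
        k1 = rohrer_k1(d)
        k2 = rohrer_k2(d, mc[32])
        rrs = (k1 + 0.72) + (k2 + 0.44) * abs(vdot_l)
        ppl = -rrs * vdot_l - sigma_l

    # Diaphragm: Hill active pressure on the volume-mapped length scale,
    # quadratic passive recoil above the FRC volume, viscous loss.
    ratio = (1.0 - mc[9]) * v_di / mc[10] + mc[9]
    z = (ratio - 1.05) / 0.192
    ffl_di = _safe_exp(-0.5 * z * z)
    ffv_di = hill_fv(vdot_di / mc[11])
    psv = 0.0
    if v_di > mc[6]:
        dv = v_di - mc[6]
        psv = mc[7] * dv * dv
    sigma_di = u_di * mc[5] * ffl_di * ffv_di + psv + mc[8] * vdot_di

    # Abdominal wall: Laplace conversion of Hill muscle tension plus linear
    # passive recoil and viscous loss.
    rt, rs, lce, dld = _geom_eval(v_ab, gv0, gdv, rt_tab, lce_tab, dld_tab, mc[36])
    za = (lce / mc[17] - 1.05) / 0.192
    ffl_ab = _safe_exp(-0.5 * za * za)
    ldot = dld * vdot_ab
    ffv_ab = hill_fv(ldot / mc[18])
    sigma_ab = (u_ab * mc[15] * ffl_ab * ffv_ab * (mc[16] / rt + mc[16] / rs)
                + (v_ab - mc[12]) / mc[13] + mc[14] * vdot_ab)

    # Rib cage: logistic recoil oriented for positive compliance.
    lo = v_rc - mc[21]
    hi = mc[22] - v_rc
    if lo < 1e-6:
        lo = 1e-6
    if hi < 1e-6:
        hi = 1e-6
    sigma_rc = mc[19] * math.log(lo / hi) + mc[20] + mc[23] * vdot_rc

    # Intercostal / accessory muscles.
    pica_di = 0.0
    if v_di < mc[6]:
        pica_di = u_di * mc[27] * (v_di - mc[6]) / (mc[24] - mc[6])
    pica_ab = u_ab * (mc[28] + (v_rc - mc[30]) / (mc[31] - mc[30]) * (mc[29] - mc[28]))
    pica = pica_di + pica_ab

    # Zone-of-apposition fraction.
    num = v_di - mc[24]
    if num < 0.0:
        num = 0.0
    fa = num / (num + v_l) / (1.0 + c1) + mc[25]

    r_rc = ppl + fa * sigma_di + mc[26] * sigma_di + pica - sigma_rc
    r_di = sigma_ab - ppl - sigma_di
    return (r_rc, r_di, vdot_l, ppl, sigma_l, sigma_di, sigma_ab, sigma_rc,
            pica, fa, v_l, v_rc)


@njit(cache=True, fastmath=True)
def mech_solve(v_di, v_ab, u_di, u_ab, u_lm, mc,
               gv0, gdv, rt_tab, lce_tab, dld_tab, warm):
    """Solve the implicit balance equations for the state rates.

    warm : float64[3] -- warm-start cache (V'di, V'ab, Ppl), updated in place.
    Returns (vdot_di, vdot_ab, vdot_l, ppl, ok).
    """
    d = glottal_diameter_mm(u_lm, mc[32])
    closed = d < mc[33]
    tol = 1e-10
    for attempt in range(3):
        if attempt == 0:
            if closed:
                x0 = warm[0]
                x1 = warm[2]
            else:
                x0 = warm[0]
                x1 = warm[1]
        elif attempt == 1:
            x0 = 0.0
            if closed:
                r = mech_residuals(0.0, 0.0, closed, v_di, v_ab, u_di, u_ab, d,
                                   mc, gv0, gdv, rt_tab, lce_tab, dld_tab)
                x1 = r[6] - r[5]  # static estimate: sigma_ab - sigma_di
            else:
                x1 = 0.0
        else:
            x0 = -0.1
            x1 = 10.0 if closed else 0.1
        ok = False
        r0, r1 = 0.0, 0.0
        for _ in range(60):
            res = mech_residuals(x0, x1, closed, v_di, v_ab, u_di, u_ab, d,
                                 mc, gv0, gdv, rt_tab, lce_tab, dld_tab)
            r0, r1 = res[0], res[1]
            err = abs(r0) + abs(r1)
            if err < tol:
                ok = True
                break
            e0 = 1e-7 * (1.0 + abs(x0))
            e1 = 1e-7 * (1.0 + abs(x1))
            ra = mech_residuals(x0 + e0, x1, closed, v_di, v_ab, u_di, u_ab, d,
                                mc, gv0, gdv, rt_tab, lce_tab, dld_tab)
            rb = mech_residuals(x0, x1 + e1, closed, v_di, v_ab, u_di, u_ab, d,
                                mc, gv0, gdv, rt_tab, lce_tab, dld_tab)
            j00 = (ra[0] - r0) / e0
            j10 = (ra[1] - r1) / e0
            j01 = (rb[0] - r0) / e1
            j11 = (rb[1] - r1) / e1
            det = j00 * j11 - j01 * j10
            if abs(det) < 1e-14:
                break
            dx0 = -(r0 * j11 - r1 * j01) / det
            dx1 = -(j00 * r1 - j10 * r0) / det
            lam = 1.0
            improved = False
            for _ls in range(12):
                t0 = x0 + lam * dx0
                t1 = x1 + lam * dx1
                rt_ = mech_residuals(t0, t1, closed, v_di, v_ab, u_di, u_ab, d,
                                     mc, gv0, gdv, rt_tab, lce_tab, dld_tab)
                if abs(rt_[0]) + abs(rt_[1]) < err:
                    x0, x1 = t0, t1
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                x0 += dx0
                x1 += dx1
        if ok:
            break
    res = mech_residuals(x0, x1, closed, v_di, v_ab, u_di, u_ab, d,
                         mc, gv0, gdv, rt_tab, lce_tab, dld_tab)
    if closed:
        vdot_di = x0
        vdot_ab = -(1.0 + mc[0]) * x0
        ppl = x1
    else:
        vdot_di = x0
        vdot_ab = x1
        ppl = res[3]
    warm[0] = vdot_di
    warm[1] = vdot_ab
    warm[2] = ppl
    return vdot_di, vdot_ab, res[2], ppl, ok


@njit(cache=True, fastmath=True)
def mech_rk4_step(y, u_di, u_ab, u_lm, dt, mc,
                  gv0, gdv, rt_tab, lce_tab, dld_tab, warm):
    """Advance the mechanical state (V_di, V_ab) by one RK4 step of dt (s)."""
    a1, b1, _, _, ok1 = mech_solve(y[0], y[1], u_di, u_ab, u_lm, mc,
                                   gv0, gdv, rt_tab, lce_tab, dld_tab, warm)
    a2, b2, _, _, ok2 = mech_solve(y[0] + 0.5 * dt * a1, y[1] + 0.5 * dt * b1,
                                   u_di, u_ab, u_lm, mc,
                                   gv0, gdv, rt_tab, lce_tab, dld_tab, warm)
    a3, b3, _, _, ok3 = mech_solve(y[0] + 0.5 * dt * a2, y[1] + 0.5 * dt * b2,
                                   u_di, u_ab, u_lm, mc,
                                   gv0, gdv, rt_tab, lce_tab, dld_tab, warm)
    a4, b4, _, _, ok4 = mech_solve(y[0] + dt * a3, y[1] + dt * b3,
                                   u_di, u_ab, u_lm, mc,
                                   gv0, gdv, rt_tab, lce_tab, dld_tab, warm)
    y[0] += dt * (a1 + 2.0 * a2 + 2.0 * a3 + a4) / 6.0
    y[1] += dt * (b1 + 2.0 * b2 + 2.0 * b3 + b4) / 6.0
    return ok1 and ok2 and ok3 and ok4


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def network_advance(
    nsteps, step0, dt_ms,
    # neuron state
    E, TH, GK, TH0, tmem, b_spike, egk, c_adapt, eth, noise_sd, dc,
    silenced, pop_of,
    # burster population (slice and parameters)
    burst_lo, burst_hi, h_state, m_state, bp,
    # synapses
    g, syn_eq, syn_decay, syn_conducts, gate_slot_of_syn, pre_slot_of_syn,
    q, q_decay, e_k,
    # terminal CSR
    tptr, ttgt, tsyn, tdel, tw_eff,
    buf, cur_ptr,
    # lung afferent coupling; off_lo/off_hi delimit the inspiratory
    # off-switch population whose rate gates early burst termination
    psr_lo, psr_hi, def_lo, def_hi, dis_lo, dis_hi, afferent_on,
    off_lo, off_hi,
    # mechanics
    mc, gv0, gdv, rt_tab, lce_tab, dld_tab, my, warm, mech_sub,
    # motor coupling
    motor_lo, motor_hi, sm_rates, rate_alpha, x_phr, x_lum, x_ilm, x_elm,
    gain_di, gain_ab,
    # cough-receptor fiber stimulus
    stim_on, stim_p, n_fibers, fptr, ftgt, fsyn, fdel, fw,
    # per-step standard-normal noise (n_steps, n)
    noise_buf,
    # outputs (chunk-local columns)
    out_counts, out_mech, out_rates,
):
    """Advance the coupled network + mechanics by nsteps of dt_ms.

    Per step: motor activations are formed from the smoothed firing rates,
    the mechanics advances by `mech_sub` RK4 substeps, lung-volume afferent
    biases are refreshed, delayed spikes are delivered, and every neuron is
    updated (exponential Euler), emitting new spikes into the ring buffer.
    """
    n = E.shape[0]
    n_syn = syn_eq.shape[0]
    dslots = buf.shape[0]
    dt_s = dt_ms * 1e-3
    cur = cur_ptr[0]
    vdot_l = 0.0
    ppl = 0.0
    for istep in range(nsteps):
        # ---- motor drive from smoothed rates of PHR, PHR-HT, LUM, LUM-HT,
        # ILM, ELM ----
        u_di = gain_di * (0.3 * sm_rates[0] + 0.7 * sm_rates[1]) / x_phr
        if u_di < 0.0:
            u_di = 0.0
        elif u_di > 1.0:
            u_di = 1.0
        u_ab = gain_ab * (0.3 * sm_rates[2] + 0.7 * sm_rates[3]) / x_lum
        if u_ab < 0.0:
            u_ab = 0.0
        elif u_ab > 1.0:
            u_ab = 1.0
        u_lm = sm_rates[4] / x_ilm - sm_rates[5] / x_elm
        if u_lm < -1.0:
            u_lm = -1.0
        elif u_lm > 1.0:
            u_lm = 1.0

        # ---- mechanics substeps ----
        hsub = dt_s / mech_sub
        for _s in range(mech_sub):
            mech_rk4_step(my, u_di, u_ab, u_lm, hsub, mc,
                          gv0, gdv, rt_tab, lce_tab, dld_tab, warm)
        vdot_di, vdot_ab, vdot_l, ppl, _ok = mech_solve(
            my[0], my[1], u_di, u_ab, u_lm, mc,
            gv0, gdv, rt_tab, lce_tab, dld_tab, warm)
        d_now = glottal_diameter_mm(u_lm, mc[32])
        closed_now = d_now < mc[33]
        if closed_now:
            obs = mech_residuals(vdot_di, ppl, True, my[0], my[1], u_di, u_ab,
                                 d_now, mc, gv0, gdv, rt_tab, lce_tab, dld_tab)
        else:
            obs = mech_residuals(vdot_di, vdot_ab, False, my[0], my[1], u_di,
                                 u_ab, d_now, mc, gv0, gdv, rt_tab, lce_tab,
                                 dld_tab)
        sigma_di = obs[5]
        sigma_ab = obs[6]
        v_l = obs[10]
        sigma_l = obs[4]
        p_alv = ppl + sigma_l
        pct_vc = 100.0 * (v_l - mc[35]) / mc[34]

        # ---- afferent biases (mV) from lung volume in %VC ----
        bias_psr = 0.5 * pct_vc
        bias_def = -0.225 * (pct_vc - 70.0)
        bias_dis = 0.0
        if pct_vc < 10.0:
            bias_dis = -1.75 * (pct_vc - 10.0)
        if not afferent_on:
            bias_psr = 0.0
            bias_def = 0.0
            bias_dis = 0.0

        # ---- fused sweep: deliver due spikes, decay conductances and
        # gates, update every neuron ----
        for i in range(n):
            # presynaptic gating variables first
            for s in range(n_syn):
                pslot = pre_slot_of_syn[s]
                if pslot >= 0:
                    w = buf[cur, i, s]
                    if w != 0.0:
                        qv = q[i, pslot] + w * (1.0 - q[i, pslot])
                        q[i, pslot] = 1.0 if qv > 1.0 else qv
                        buf[cur, i, s] = 0.0
            for pslot in range(q.shape[1]):
                q[i, pslot] *= q_decay[pslot]
            gtot = 0.0
            ge = 0.0
            for s in range(n_syn):
                if syn_conducts[s]:
                    w = buf[cur, i, s]
                    gv = g[i, s]
                    if w != 0.0:
                        gslot = gate_slot_of_syn[s]
                        if gslot >= 0:
                            w *= 1.0 - q[i, gslot]
                        gv += w
                        buf[cur, i, s] = 0.0
                    gv *= syn_decay[s]
                    g[i, s] = gv
                    gtot += gv
                    ge += gv * syn_eq[s]
            gk = GK[i]
            gtot += gk
            ge += gk * e_k
            bias = 0.0
            if psr_lo <= i < psr_hi:
                bias = bias_psr
            elif def_lo <= i < def_hi:
                bias = bias_def
            elif dis_lo <= i < dis_hi:
                bias = bias_dis
            if burst_lo <= i < burst_hi:
                # Slow inward (persistent-sodium-like) current with
                # population-shared gates: activation m charges with
                # population spiking (afterdepolarisation, decay tau_m);
                # the slow inactivation gate is hysteretic -- it conducts
                # while available (h above the release threshold reached
                # after recovery) and shuts fully once population spiking
                # depletes h below the cut-off, recovering linearly.
                if h_state[1] > 0.5:
                    gn = bp[0] * (bp[2] + (1.0 - bp[2]) * m_state[0]) * h_state[0]
                    gtot += gn
                    ge += gn * bp[5]
            denom = 1.0 + gtot
            e_inf = (ge + dc[i] + bias) / denom
            decay = _safe_exp(-denom * dt_ms / tmem[i])
            e_new = e_inf + (E[i] - e_inf) * decay
            ns = noise_sd[i]
            if ns > 0.0:
                e_new += ns * noise_buf[istep, i]
            target = TH0[i] + c_adapt[i] * e_new
            TH[i] = target + (TH[i] - target) * eth[i]
            GK[i] = gk * egk[i]
            E[i] = e_new
            if e_new >= TH[i] and silenced[i] == 0:
                GK[i] += b_spike[i]
                out_counts[pop_of[i], istep] += 1
                for t in range(tptr[i], tptr[i + 1]):
                    slot = cur + tdel[t]
                    if slot >= dslots:
                        slot -= dslots
                    buf[slot, ttgt[t], tsyn[t]] += tw_eff[t]

        # ---- shared burster gate update from the population spike count ----
        if burst_hi > burst_lo:
            if off_hi > off_lo:
                # smoothed mean rate of the off-switch population
                # (spikes/s, tau 100 ms)
                inst_off = (float(out_counts[pop_of[off_lo], istep])
                            / ((off_hi - off_lo) * dt_s))
                m_state[1] += (inst_off - m_state[1]) * (dt_ms / 100.0)
            frac = float(out_counts[pop_of[burst_lo], istep]) / (burst_hi - burst_lo)
            m0_ = m_state[0]
            m0_ += bp[1] * (1.0 - m0_) * frac
            m0_ -= m0_ * (dt_ms / bp[4])
            m_state[0] = m0_
            h0_ = h_state[0]
            if h_state[1] > 0.5:
                h0_ *= 1.0 - bp[3] * frac
                if h0_ < bp[8]:
                    h_state[1] = 0.0
                elif bp[9] > 0.0 and h0_ < bp[7] - 0.02 and off_hi > off_lo:
                    # early burst termination by the inspiratory off-switch:
                    # once the burst is under way, sustained firing of the
                    # volume-gated off-switch population above threshold
                    # completes the inactivation.  The off-switch loses its
                    # afferent drive under vagotomy and is inhibited by the
                    # second-order cough population during coughing.
                    if m_state[1] > bp[9]:
                        h_state[1] = 0.0
                        h0_ = bp[10]
            else:
                h0_ += dt_ms / bp[6]
                if h0_ >= bp[7]:
                    h_state[1] = 1.0
            if h0_ > 1.0:
                h0_ = 1.0
            h_state[0] = h0_

        # ---- cough-receptor fiber stimulus ----
        if stim_on:
            for fb in range(n_fibers):
                if np.random.random() < stim_p:
                    for t in range(fptr[fb], fptr[fb + 1]):
                        slot = cur + fdel[t]
                        if slot >= dslots:
                            slot -= dslots
                        buf[slot, ftgt[t], fsyn[t]] += fw[t]

        # ---- smoothed motor rates (mean per-neuron spikes/s) ----
        # motor_lo[m] is the population index, motor_hi[m] its size.
        for m in range(6):
            cnt = float(out_counts[motor_lo[m], istep])
            inst = cnt / (float(motor_hi[m]) * dt_s)
            sm_rates[m] += (inst - sm_rates[m]) * rate_alpha

        # ---- record mechanics ----
        out_mech[0, istep] = v_l
        out_mech[1, istep] = -vdot_l
        out_mech[2, istep] = p_alv
        out_mech[3, istep] = ppl
        out_mech[4, istep] = my[0]
        out_mech[5, istep] = my[1]
        out_mech[6, istep] = vdot_di
        out_mech[7, istep] = vdot_ab
        out_mech[8, istep] = u_di
        out_mech[9, istep] = u_ab
        out_mech[10, istep] = u_lm
        out_mech[11, istep] = sigma_di
        out_mech[12, istep] = sigma_ab
        out_mech[13, istep] = pct_vc
        for m in range(6):
            out_rates[m, istep] = sm_rates[m]

        cur += 1
        if cur >= dslots:
            cur = 0
    cur_ptr[0] = cur
    return 0
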