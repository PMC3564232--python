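"""Numba kernels: fixed-step RK2 integration of the three spiking networks.

All membrane equations are in mV / ms / uA/cm2; synaptic conductances are passed
to the kernels already converted to mS/cm2 of the target compartment.  Spikes are
upward crossings of +10 mV of the (axo-)somatic potential, detected once per
crossing.  Presynaptic spikes increment the postsynaptic aggregate gating
variables at the end of the step in which they occur; aggregate variables decay
exponentially (NMDA uses the saturating two-variable scheme).
"""

import numpy as np
from numba import njit

SPIKE_THRESHOLD = 10.0  # mV, presynaptic detection threshold for every cell class

# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _linexp(x, k):
    """x / (1 - exp(-x/k)), stable near x = 0."""
    if abs(x) < 1e-7:
        return k
    return x / (1.0 - np.exp(-x / k))


@njit(cache=True, fastmath=True)
def _mg_block(v):
    # 1 mM [Mg2+]; Jahr & Stevens form used by the cortical NMDA scheme
    return 1.0 / (1.0 + 0.2801 * np.exp(-0.062 * v))


# ---------------------------------------------------------------------------
# cell derivatives
# ---------------------------------------------------------------------------
# Compte-type cortical pyramidal cell parameter vector layout:
# [0] g_Na [1] E_Na [2] g_K [3] E_K [4] g_A [5] g_KS [6] g_Ca [7] E_Ca
# [8] g_KCa [9] KD_Ca [10] alpha_Ca [11] tau_Ca [12] g_NaP [13] g_AR
# [14] g_KNa [15] alpha_Na [16] R_pump [17] Na_eq [18] Na_half [19] phi
# [20] Cm [21] area_soma/area_dend


@njit(cache=True, fastmath=True)
def _d_compte_py(Vs, Vd, h, n, hA, mKS, Ca, Na, gL, EL, gsd_s, gsd_d,
                 Is_syn, Id_syn, Id_inj, P):
    gNa, ENa, gK, EK = P[0], P[1], P[2], P[3]
    phi, Cm = P[19], P[20]
    # --- axo-somatic currents
    am = 0.1 * _linexp(Vs + 33.0, 10.0)
    bm = 4.0 * np.exp(-(Vs + 53.7) / 12.0)
    minf = am / (am + bm)
    INa = gNa * minf * minf * minf * h * (Vs - ENa)
    ah = 0.07 * np.exp(-(Vs + 50.0) / 10.0)
    bh = 1.0 / (1.0 + np.exp(-(Vs + 20.0) / 10.0))
    dh = phi * (ah * (1.0 - h) - bh * h)
    an = 0.01 * _linexp(Vs + 34.0, 10.0)
    bn = 0.125 * np.exp(-(Vs + 44.0) / 25.0)
    IK = gK * n * n * n * n * (Vs - EK)
    dn = phi * (an * (1.0 - n) - bn * n)
    mA = 1.0 / (1.0 + np.exp(-(Vs + 50.0) / 20.0))
    hAinf = 1.0 / (1.0 + np.exp((Vs + 80.0) / 6.0))
    IA = P[4] * mA * mA * mA * hA * (Vs - EK)
    dhA = (hAinf - hA) / 15.0
    mKSinf = 1.0 / (1.0 + np.exp(-(Vs + 34.0) / 6.5))
    tKS = 8.0 / (np.exp(-(Vs + 55.0) / 30.0) + np.exp((Vs + 55.0) / 30.0))
    IKS = P[5] * mKS * (Vs - EK)
    dmKS = (mKSinf - mKS) / tKS
    ILs = gL * (Vs - EL)
    # --- dendritic currents
    mCa = 1.0 / (1.0 + np.exp(-(Vd + 20.0) / 9.0))
    ICa = P[6] * mCa * mCa * (Vd - P[7])
    IKCa = P[8] * (Ca / (Ca + P[9])) * (Vd - EK)
    mNaP = 1.0 / (1.0 + np.exp(-(Vd + 55.7) / 7.7))
    INaP = P[12] * mNaP * mNaP * mNaP * (Vd - ENa)
    hAR = 1.0 / (1.0 + np.exp((Vd + 75.0) / 4.0))
    IAR = P[13] * hAR * (Vd - EK)
    wKNa = 0.37 / (1.0 + (38.7 / Na) ** 3.5)
    IKNa = P[14] * wKNa * (Vd - EK)
    ILd = gL * (Vd - EL)
    # --- ion dynamics (single dendritic Na pool; somatic Na influx scaled by area)
    dCa = -P[10] * ICa - Ca / P[11]
    na3 = Na * Na * Na
    nah3 = P[18] * P[18] * P[18]
    naeq = P[17]
    naeq3 = naeq * naeq * naeq
    pump = P[16] * (na3 / (na3 + nah3) - naeq3 / (naeq3 + nah3))
    dNa = P[15] * (-INa * P[21] - INaP) - pump
    dVs = (-ILs - INa - IK - IA - IKS - gsd_s * (Vs - Vd) - Is_syn) / Cm
    dVd = (-ILd - ICa - IKCa - INaP - IAR - IKNa - gsd_d * (Vd - Vs)
           - Id_syn + Id_inj) / Cm
    return dVs, dVd, dh, dn, dhA, dmKS, dCa, dNa


# Wang-Buzsaki interneuron parameter vector: [0] g_Na [1] E_Na [2] g_K [3] E_K
# [4] phi [5] Cm


@njit(cache=True, fastmath=True)
def _d_wb(V, h, n, gL, EL, Isyn, Iinj, P):
    gNa, ENa, gK, EK, phi, Cm = P[0], P[1], P[2], P[3], P[4], P[5]
    am = 0.1 * _linexp(V + 35.0, 10.0)
    bm = 4.0 * np.exp(-(V + 60.0) / 18.0)
    minf = am / (am + bm)
    INa = gNa * minf * minf * minf * h * (V - ENa)
    ah = 0.07 * np.exp(-(V + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 28.0) / 10.0))
    dh = phi * (ah * (1.0 - h) - bh * h)
    an = 0.01 * _linexp(V + 34.0, 10.0)
    bn = 0.125 * np.exp(-(V + 44.0) / 80.0)
    IK = gK * n * n * n * n * (V - EK)
    dn = phi * (an * (1.0 - n) - bn * n)
    dV = (-gL * (V - EL) - INa - IK - Isyn + Iinj) / Cm
    return dV, dh, dn


# Pinsky-Rinzel pyramidal cell (physiological voltage scale: original shifted by
# -60 mV).  Parameter vector: [0] g_Na [1] E_Na [2] g_KDR [3] E_K [4] g_Ca
# [5] E_Ca [6] g_KC [7] g_KAHP [8] g_L [9] E_L [10] g_c [11] p_soma [12] Cm


@njit(cache=True, fastmath=True)
def _d_pr(Vs, Vd, h, n, s, c, q, Ca, Is_syn, Id_syn, Id_inj, P):
    us = Vs + 60.0
    ud = Vd + 60.0
    gc_s = P[10] / P[11]
    gc_d = P[10] / (1.0 - P[11])
    Cm = P[12]
    # soma
    am = 0.32 * _linexp(us - 13.1, 4.0)
    bm = 0.28 * _linexp(40.1 - us, 5.0)
    minf = am / (am + bm)
    INa = P[0] * minf * minf * h * (Vs - P[1])
    ah = 0.128 * np.exp((17.0 - us) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - us) / 5.0))
    dh = ah * (1.0 - h) - bh * h
    an = 0.016 * _linexp(us - 35.1, 5.0)
    bn = 0.25 * np.exp(0.5 - 0.025 * us)
    IKDR = P[2] * n * (Vs - P[3])
    dn = an * (1.0 - n) - bn * n
    # dendrite
    as_ = 1.6 / (1.0 + np.exp(-0.072 * (ud - 65.0)))
    bs = 0.02 * _linexp(51.1 - ud, 5.0)
    ICa = P[4] * s * s * (Vd - P[5])
    ds = as_ * (1.0 - s) - bs * s
    if ud <= 50.0:
        ac = np.exp((ud - 10.0) / 11.0 - (ud - 6.5) / 27.0) / 18.975
        bc = 2.0 * np.exp((6.5 - ud) / 27.0) - ac
    else:
        ac = 2.0 * np.exp((6.5 - ud) / 27.0)
        bc = 0.0
    chi = Ca / 250.0
    if chi > 1.0:
        chi = 1.0
    IKC = P[6] * c * chi * (Vd - P[3])
    dc = ac * (1.0 - c) - bc * c
    aq = 0.00002 * Ca
    if aq > 0.01:
        aq = 0.01
    IKAHP = P[7] * q * (Vd - P[3])
    dq = aq * (1.0 - q) - 0.001 * q
    dCa = -0.13 * ICa - 0.075 * Ca
    dVs = (-P[8] * (Vs - P[9]) - INa - IKDR + gc_s * (Vd - Vs) - Is_syn) / Cm
    dVd = (-P[8] * (Vd - P[9]) - ICa - IKC - IKAHP + gc_d * (Vs - Vd)
           - Id_syn + Id_inj) / Cm
    return dVs, dVd, dh, dn, ds, dc, dq, dCa


# ---------------------------------------------------------------------------
# cortical network (Compte-type PY + WB IN, AMPA/NMDA/GABA with aggregate gating)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def run_cortex(dt, n_steps, rec_stride,
               P_py, P_in,
               gL_py, EL_py, gsd_s, gsd_d, gL_in, EL_in,
               # channel conductance densities (mS/cm2 of target compartment)
               g_ampa_pp, g_nmda_pp, g_gaba_ip,
               g_ampa_pi, g_nmda_pi, g_gaba_ii,
               E_ampa, E_gaba, tau_ampa, tau_gaba,
               tau_nmda_s, r_nmda,
               pp_indptr, pp_idx, pp_w,
               pi_indptr, pi_idx, pi_w,
               ip_indptr, ip_idx, ip_w,
               ii_indptr, ii_idx, ii_w,
               ext_steps, ext_tgt, ext_w,
               Iapp_py, sigma_py, Iapp_in, sigma_in, seed,
               Vs, Vd, h, n, hA, mKS, Ca, Na,
               Vi, hi, ni,
               s_ampa_py, s_nmda_py, x_nmda_py, s_gaba_py,
               s_ampa_in, s_nmda_in, x_nmda_in, s_gaba_in,
               spk_py_step, spk_py_idx, spk_in_step, spk_in_idx,
               lfp, v_rec, rec_py):
    np.random.seed(seed)
    n_py = Vs.shape[0]
    n_in = Vi.shape[0]
    f_a = np.exp(-dt / tau_ampa)
    fh_a = np.exp(-0.5 * dt / tau_ampa)
    f_g = np.exp(-dt / tau_gaba)
    fh_g = np.exp(-0.5 * dt / tau_gaba)
    f_n = np.exp(-dt / tau_nmda_s)
    fh_n = np.exp(-0.5 * dt / tau_nmda_s)
    sq = 1.0 / np.sqrt(dt)
    c_py = 0
    c_in = 0
    n_ext = ext_steps.shape[0]
    i_ext = 0
    thr = SPIKE_THRESHOLD
    for t in range(n_steps):
        # -- pyramidal cells
        for i in range(n_py):
            noise = Iapp_py[i]
            if sigma_py[i] > 0.0:
                noise += sigma_py[i] * sq * np.random.normal()
            v0s = Vs[i]
            v0d = Vd[i]
            sa = s_ampa_py[i]
            sn = s_nmda_py[i]
            xn = x_nmda_py[i]
            sg = s_gaba_py[i]
            # stage 1
            Is1 = g_gaba_ip * sg * (v0s - E_gaba)
            Id1 = (g_ampa_pp * sa * (v0d - E_ampa)
                   + g_nmda_pp * sn * _mg_block(v0d) * (v0d - E_ampa))
            k = _d_compte_py(v0s, v0d, h[i], n[i], hA[i], mKS[i], Ca[i], Na[i],
                             gL_py[i], EL_py[i], gsd_s[i], gsd_d[i],
                             Is1, Id1, noise, P_py)
            hdt = 0.5 * dt
            v1s = v0s + hdt * k[0]
            v1d = v0d + hdt * k[1]
            h1 = h[i] + hdt * k[2]
            n1 = n[i] + hdt * k[3]
            hA1 = hA[i] + hdt * k[4]
            mKS1 = mKS[i] + hdt * k[5]
            Ca1 = Ca[i] + hdt * k[6]
            Na1 = Na[i] + hdt * k[7]
            Is2 = g_gaba_ip * sg * fh_g * (v1s - E_gaba)
            Id2 = (g_ampa_pp * sa * fh_a * (v1d - E_ampa)
                   + g_nmda_pp * sn * fh_n * _mg_block(v1d) * (v1d - E_ampa))
            k2 = _d_compte_py(v1s, v1d, h1, n1, hA1, mKS1, Ca1, Na1,
                              gL_py[i], EL_py[i], gsd_s[i], gsd_d[i],
                              Is2, Id2, noise, P_py)
            vns = v0s + dt * k2[0]
            Vs[i] = vns
            Vd[i] = v0d + dt * k2[1]
            h[i] += dt * k2[2]
            n[i] += dt * k2[3]
            hA[i] += dt * k2[4]
            mKS[i] += dt * k2[5]
            Ca[i] += dt * k2[6]
            Na[i] += dt * k2[7]
            if v0s < thr and vns >= thr and c_py < spk_py_step.shape[0]:
                spk_py_step[c_py] = t
                spk_py_idx[c_py] = i
                c_py += 1
        # -- interneurons
        for i in range(n_in):
            noise = Iapp_in[i]
            if sigma_in[i] > 0.0:
                noise += sigma_in[i] * sq * np.random.normal()
            v0 = Vi[i]
            sa = s_ampa_in[i]
            sn = s_nmda_in[i]
            xn = x_nmda_in[i]
            sg = s_gaba_in[i]
            Is1 = (g_ampa_pi * sa * (v0 - E_ampa)
                   + g_nmda_pi * sn * _mg_block(v0) * (v0 - E_ampa)
                   + g_gaba_ii * sg * (v0 - E_gaba))
            k = _d_wb(v0, hi[i], ni[i], gL_in[i], EL_in[i], Is1, noise, P_in)
            hdt = 0.5 * dt
            v1 = v0 + hdt * k[0]
            h1 = hi[i] + hdt * k[1]
            n1 = ni[i] + hdt * k[2]
            Is2 = (g_ampa_pi * sa * fh_a * (v1 - E_ampa)
                   + g_nmda_pi * sn * fh_n * _mg_block(v1) * (v1 - E_ampa)
                   + g_gaba_ii * sg * fh_g * (v1 - E_gaba))
            k2 = _d_wb(v1, h1, n1, gL_in[i], EL_in[i], Is2, noise, P_in)
            vn = v0 + dt * k2[0]
            Vi[i] = vn
            hi[i] += dt * k2[1]
            ni[i] += dt * k2[2]
            if v0 < thr and vn >= thr and c_in < spk_in_step.shape[0]:
                spk_in_step[c_in] = t
                spk_in_idx[c_in] = i
                c_in += 1
        # -- synaptic decay
        for i in range(n_py):
            s_ampa_py[i] *= f_a
            s_gaba_py[i] *= f_g
            s_nmda_py[i] *= f_n
        for i in range(n_in):
            s_ampa_in[i] *= f_a
            s_gaba_in[i] *= f_g
            s_nmda_in[i] *= f_n
        # -- deliver this step's spikes
        j0 = c_py
        while j0 > 0 and spk_py_step[j0 - 1] == t:
            j0 -= 1
        for j in range(j0, c_py):
            src = spk_py_idx[j]
            for e in range(pp_indptr[src], pp_indptr[src + 1]):
                tgt = pp_idx[e]
                s_ampa_py[tgt] += pp_w[e]
                s_nmda_py[tgt] += pp_w[e] * r_nmda
            for e in range(pi_indptr[src], pi_indptr[src + 1]):
                tgt = pi_idx[e]
                s_ampa_in[tgt] += pi_w[e]
                s_nmda_in[tgt] += pi_w[e] * r_nmda
        j0 = c_in
        while j0 > 0 and spk_in_step[j0 - 1] == t:
            j0 -= 1
        for j in range(j0, c_in):
            src = spk_in_idx[j]
            for e in range(ip_indptr[src], ip_indptr[src + 1]):
                s_gaba_py[ip_idx[e]] += ip_w[e]
            for e in range(ii_indptr[src], ii_indptr[src + 1]):
                s_gaba_in[ii_idx[e]] += ii_w[e]
        # -- external protocol events (single-cell use: AMPA onto PY dendrite)
        while i_ext < n_ext and ext_steps[i_ext] == t:
            s_ampa_py[ext_tgt[i_ext]] += ext_w[i_ext]
            i_ext += 1
        # -- recordings
        if (t + 1) % rec_stride == 0:
            fr = (t + 1) // rec_stride - 1
            acc = 0.0
            for i in range(n_py):
                acc += abs(g_ampa_pp * s_ampa_py[i] * (Vd[i] - E_ampa))
                acc += abs(g_nmda_pp * s_nmda_py[i] * _mg_block(Vd[i])
                           * (Vd[i] - E_ampa))
                acc += abs(g_gaba_ip * s_gaba_py[i] * (Vs[i] - E_gaba))
            for i in range(n_in):
                acc += abs(g_ampa_pi * s_ampa_in[i] * (Vi[i] - E_ampa))
                acc += abs(g_nmda_pi * s_nmda_in[i] * _mg_block(Vi[i])
                           * (Vi[i] - E_ampa))
                acc += abs(g_gaba_ii * s_gaba_in[i] * (Vi[i] - E_gaba))
            lfp[fr] = acc
            for r in range(rec_py.shape[0]):
                v_rec[fr, r] = Vs[rec_py[r]]
    return c_py, c_in


# ---------------------------------------------------------------------------
# CA network (Pinsky-Rinzel PY + WB IN), four aggregate channels per population:
# ch0 = excitation from local PY, ch1 = inhibition from local IN,
# ch2 = external stream 1 (mossy fibers or Schaffer collaterals),
# ch3 = external stream 2 (temporoammonic input).
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def run_ca(dt, n_steps, rec_stride,
           P_pr, P_in, gL_in, EL_in,
           # channel parameter vectors, length 4 each
           g_py, E_py, tau_py, comp_py,      # comp: 0 soma, 1 dend
           g_in, E_in, tau_in,
           # local wiring
           pp_indptr, pp_idx, pp_w,
           pi_indptr, pi_idx, pi_w,
           ip_indptr, ip_idx, ip_w,
           ii_indptr, ii_idx, ii_w,
           # external stream 1: presynaptic spike list + wiring onto ch2
           e1_steps, e1_src, e1_w,
           e1p_indptr, e1p_idx, e1p_w,
           e1i_indptr, e1i_idx, e1i_w,
           # external stream 2 onto ch3
           e2_steps, e2_src, e2_w,
           e2p_indptr, e2p_idx, e2p_w,
           e2i_indptr, e2i_idx, e2i_w,
           Iapp_py, sigma_py, Iapp_in, sigma_in, seed,
           Vs, Vd, h, n, s, c, q, Ca,
           Vi, hi, ni,
           S_py, S_in,                       # (4, n_py), (4, n_in) gating
           spk_py_step, spk_py_idx, spk_in_step, spk_in_idx,
           site_py, site_in,                 # index arrays of recording-site cells
           site_g_py, site_g_in,             # per-channel weights for the LFP sum
           site_sig, vin_site, site_s_rec, v_rec, rec_py):
    np.random.seed(seed)
    n_py = Vs.shape[0]
    n_in = Vi.shape[0]
    f_py = np.empty(4)
    fh_py = np.empty(4)
    f_in = np.empty(4)
    fh_in = np.empty(4)
    for ch in range(4):
        f_py[ch] = np.exp(-dt / tau_py[ch])
        fh_py[ch] = np.exp(-0.5 * dt / tau_py[ch])
        f_in[ch] = np.exp(-dt / tau_in[ch])
        fh_in[ch] = np.exp(-0.5 * dt / tau_in[ch])
    sq = 1.0 / np.sqrt(dt)
    c_py = 0
    c_in = 0
    i_e1 = 0
    i_e2 = 0
    n_e1 = e1_steps.shape[0]
    n_e2 = e2_steps.shape[0]
    thr = SPIKE_THRESHOLD
    hdt = 0.5 * dt
    for t in range(n_steps):
        for i in range(n_py):
            noise = Iapp_py[i]
            if sigma_py[i] > 0.0:
                noise += sigma_py[i] * sq * np.random.normal()
            v0s = Vs[i]
            v0d = Vd[i]
            # stage 1 synaptic currents
            Gs = 0.0
            GEs = 0.0
            Gd = 0.0
            GEd = 0.0
            for ch in range(4):
                gs = g_py[ch] * S_py[ch, i]
                if comp_py[ch] == 0:
                    Gs += gs
                    GEs += gs * E_py[ch]
                else:
                    Gd += gs
                    GEd += gs * E_py[ch]
            Is1 = Gs * v0s - GEs
            Id1 = Gd * v0d - GEd
            k = _d_pr(v0s, v0d, h[i], n[i], s[i], c[i], q[i], Ca[i],
                      Is1, Id1, noise, P_pr)
            v1s = v0s + hdt * k[0]
            v1d = v0d + hdt * k[1]
            h1 = h[i] + hdt * k[2]
            n1 = n[i] + hdt * k[3]
            s1 = s[i] + hdt * k[4]
            c1 = c[i] + hdt * k[5]
            q1 = q[i] + hdt * k[6]
            Ca1 = Ca[i] + hdt * k[7]
            Gs = 0.0
            GEs = 0.0
            Gd = 0.0
            GEd = 0.0
            for ch in range(4):
                gs = g_py[ch] * S_py[ch, i] * fh_py[ch]
                if comp_py[ch] == 0:
                    Gs += gs
                    GEs += gs * E_py[ch]
                else:
                    Gd += gs
                    GEd += gs * E_py[ch]
            Is2 = Gs * v1s - GEs
            Id2 = Gd * v1d - GEd
            k2 = _d_pr(v1s, v1d, h1, n1, s1, c1, q1, Ca1, Is2, Id2, noise, P_pr)
            vns = v0s + dt * k2[0]
            Vs[i] = vns
            Vd[i] += dt * k2[1]
            h[i] += dt * k2[2]
            n[i] += dt * k2[3]
            s[i] += dt * k2[4]
            c[i] += dt * k2[5]
            q[i] += dt * k2[6]
            Ca[i] += dt * k2[7]
            if v0s < thr and vns >= thr and c_py < spk_py_step.shape[0]:
                spk_py_step[c_py] = t
                spk_py_idx[c_py] = i
                c_py += 1
        for i in range(n_in):
            noise = Iapp_in[i]
            if sigma_in[i] > 0.0:
                noise += sigma_in[i] * sq * np.random.normal()
            v0 = Vi[i]
            Is1 = 0.0
            for ch in range(4):
                Is1 += g_in[ch] * S_in[ch, i] * (v0 - E_in[ch])
            k = _d_wb(v0, hi[i], ni[i], gL_in[i], EL_in[i], Is1, noise, P_in)
            v1 = v0 + hdt * k[0]
            h1 = hi[i] + hdt * k[1]
            n1 = ni[i] + hdt * k[2]
            Is2 = 0.0
            for ch in range(4):
                Is2 += g_in[ch] * S_in[ch, i] * fh_in[ch] * (v1 - E_in[ch])
            k2 = _d_wb(v1, h1, n1, gL_in[i], EL_in[i], Is2, noise, P_in)
            vn = v0 + dt * k2[0]
            Vi[i] = vn
            hi[i] += dt * k2[1]
            ni[i] += dt * k2[2]
            if v0 < thr and vn >= thr and c_in < spk_in_step.shape[0]:
                spk_in_step[c_in] = t
                spk_in_idx[c_in] = i
                c_in += 1
        # decay
        for i in range(n_py):
            for ch in range(4):
                S_py[ch, i] *= f_py[ch]
        for i in range(n_in):
            for ch in range(4):
                S_in[ch, i] *= f_in[ch]
        # local spikes
        j0 = c_py
        while j0 > 0 and spk_py_step[j0 - 1] == t:
            j0 -= 1
        for j in range(j0, c_py):
            src = spk_py_idx[j]
            for e in range(pp_indptr[src], pp_indptr[src + 1]):
                S_py[0, pp_idx[e]] += pp_w[e]
            for e in range(pi_indptr[src], pi_indptr[src + 1]):
                S_in[0, pi_idx[e]] += pi_w[e]
        j0 = c_in
        while j0 > 0 and spk_in_step[j0 - 1] == t:
            j0 -= 1
        for j in range(j0, c_in):
            src = spk_in_idx[j]
            for e in range(ip_indptr[src], ip_indptr[src + 1]):
                S_py[1, ip_idx[e]] += ip_w[e]
            for e in range(ii_indptr[src], ii_indptr[src + 1]):
                S_in[1, ii_idx[e]] += ii_w[e]
        # external streams
        while i_e1 < n_e1 and e1_steps[i_e1] == t:
            src = e1_src[i_e1]
            ew = e1_w[i_e1]
            for e in range(e1p_indptr[src], e1p_indptr[src + 1]):
                S_py[2, e1p_idx[e]] += e1p_w[e] * ew
            for e in range(e1i_indptr[src], e1i_indptr[src + 1]):
                S_in[2, e1i_idx[e]] += e1i_w[e] * ew
            i_e1 += 1
        while i_e2 < n_e2 and e2_steps[i_e2] == t:
            src = e2_src[i_e2]
            ew = e2_w[i_e2]
            for e in range(e2p_indptr[src], e2p_indptr[src + 1]):
                S_py[3, e2p_idx[e]] += e2p_w[e] * ew
            for e in range(e2i_indptr[src], e2i_indptr[src + 1]):
                S_in[3, e2i_idx[e]] += e2i_w[e] * ew
            i_e2 += 1
        # recordings
        if (t + 1) % rec_stride == 0:
            fr = (t + 1) // rec_stride - 1
            acc = 0.0
            keep_s = site_s_rec.shape[0] > fr
            for jj in range(site_py.shape[0]):
                i = site_py[jj]
                for ch in range(4):
                    acc += site_g_py[ch] * S_py[ch, i]
                    if keep_s:
                        site_s_rec[fr, jj, ch] = S_py[ch, i]
            vin = 0.0
            n_sp = site_py.shape[0]
            for jj in range(site_in.shape[0]):
                i = site_in[jj]
                vin += Vi[i]
                for ch in range(4):
                    acc += site_g_in[ch] * S_in[ch, i]
                    if keep_s:
                        site_s_rec[fr, n_sp + jj, ch] = S_in[ch, i]
            site_sig[fr] = acc
            if site_in.shape[0] > 0:
                vin_site[fr] = vin / site_in.shape[0]
            for r in range(rec_py.shape[0]):
                v_rec[fr, r] = Vs[rec_py[r]]
    return c_py, c_in
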