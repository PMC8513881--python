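"""Numba-compiled numerical cores.

Three hot paths live here: the per-ISI short-term-plasticity recurrence
fused with the Gaussian likelihood (used by the Metropolis-Hastings
sampler), the sampler itself, and the CA3 spiking-network integrator.
Everything is written against plain float64/int64 arrays so the kernels
cache cleanly across processes.

Full STP parameter vector layout (shared by all model variants)::

    0 g_max   1 tau_f   2 f0     3 a      4 tau_d   5 tau_a   6 a0
    7 b_a     8 f0_til  9 tau_f0 10 b_f0  11 tau_g  12 k_g

Times and time constants are in seconds here; the network kernel works
in milliseconds throughout.
"""

import math

import numpy as np
from numba import njit

# -- indices into the full parameter vector ---------------------------------
IG, ITAUF, IF0, IA, ITAUD, ITAUA, IA0, IBA, IF0T, ITAUF0, IBF0, ITAUG, IKG = range(13)


@njit(cache=True)
def stp_states(times, p, f_exp, d_active, a_dyn, f0_dyn, g_dyn,
               f_init, d_init, a_init, f0_init):
    """Exact per-ISI update of the STP state variables.

    Returns pre-increment states (f, d, a, f0, gdyn) at each stimulus and
    the normalised amplitude f**e * d (scaled by the dynamic conductance
    factor when active).
    """
    n = times.shape[0]
    f = np.empty(n)
    d = np.empty(n)
    av = np.empty(n)
    f0v = np.empty(n)
    gv = np.empty(n)
    amps = np.empty(n)

    fc = f_init
    dc = d_init
    ac = a_init
    f0c = f0_init
    gc = 0.0
    for i in range(n):
        f[i] = fc
        d[i] = dc
        av[i] = ac
        f0v[i] = f0c
        gv[i] = gc
        amp = fc
        if f_exp == 2:
            amp = fc * fc
        amp *= dc
        if g_dyn:
            amp *= 1.0 + gc / p[IG]
        amps[i] = amp

        # post-spike increments
        fp = fc + ac * (1.0 - fc)
        dp = dc * (1.0 - fc) if d_active else 1.0
        ap = ac + p[IBA] * (1.0 - ac) if a_dyn else ac
        f0p = f0c + p[IBF0] * (1.0 - f0c) if f0_dyn else f0c
        gp = gc + p[IKG] if g_dyn else gc

        if i == n - 1:
            break
        dt = times[i + 1] - times[i]

        if a_dyn:
            ac = p[IA0] - (p[IA0] - ap) * math.exp(-dt / p[ITAUA])
        if f0_dyn:
            f0c = p[IF0T] - (p[IF0T] - f0p) * math.exp(-dt / p[ITAUF0])
            # coupled decay of f towards the moving baseline f0(t)
            tf = p[ITAUF]
            tf0 = p[ITAUF0]
            ef = math.exp(-dt / tf)
            if abs(tf0 - tf) < 1e-12 * tf:
                f_new = p[IF0T] + (fp - p[IF0T]) * ef \
                    + (p[IF0T] - f0p) * (dt / tf) * ef
            else:
                ef0 = math.exp(-dt / tf0)
                f_new = p[IF0T] + (fp - p[IF0T]) * ef \
                    - (p[IF0T] - f0p) * (tf0 / (tf0 - tf)) * (ef0 - ef)
            fc = f_new
        else:
            fc = f0c - (f0c - fp) * math.exp(-dt / p[ITAUF])
        if d_active:
            dc = 1.0 - (1.0 - dp) * math.exp(-dt / p[ITAUD])
        else:
            dc = 1.0
        if g_dyn:
            gc = gp * math.exp(-dt / p[ITAUG])
    return f, d, av, f0v, gv, amps


@njit(cache=True)
def stp_loglik(times, y, p, f_exp, d_active, a_dyn, f0_dyn, g_dyn,
               drive, noise_scale, sd_floor, noise_mode):
    """Gaussian log-likelihood of observed amplitudes under the STP model.

    The observation model is y_n ~ N(A_n, sigma_n) with A_n the model
    amplitude in pA (g_max * normalised amplitude * driving force) and
    sigma_n = sqrt(noise_scale * A_n) when noise_mode == 1 (amplitude-
    proportional variance, the default) or noise_scale * A_n when
    noise_mode == 0 (amplitude-proportional sd). A positive floor on the
    spread guards near-zero amplitudes.
    """
    n = times.shape[0]
    fc = p[IF0T] if f0_dyn else p[IF0]
    f0c = fc
    dc = 1.0
    ac = p[IA0] if a_dyn else p[IA]
    gc = 0.0
    ll = 0.0
    log2pi = 1.8378770664093453
    for i in range(n):
        amp = fc
        if f_exp == 2:
            amp = fc * fc
        amp *= dc
        if g_dyn:
            amp *= 1.0 + gc / p[IG]
        a_pa = p[IG] * amp * drive
        if noise_mode == 1:
            sd = math.sqrt(noise_scale * a_pa) if a_pa > 0.0 else 0.0
        else:
            sd = noise_scale * a_pa
        if sd < sd_floor:
            sd = sd_floor
        r = (y[i] - a_pa) / sd
        ll += -0.5 * r * r - math.log(sd) - 0.5 * log2pi

        fp = fc + ac * (1.0 - fc)
        dp = dc * (1.0 - fc) if d_active else 1.0
        ap = ac + p[IBA] * (1.0 - ac) if a_dyn else ac
        f0p = f0c + p[IBF0] * (1.0 - f0c) if f0_dyn else f0c
        gp = gc + p[IKG] if g_dyn else gc

        if i == n - 1:
            break
        dt = times[i + 1] - times[i]
        if a_dyn:
            ac = p[IA0] - (p[IA0] - ap) * math.exp(-dt / p[ITAUA])
        if f0_dyn:
            f0c = p[IF0T] - (p[IF0T] - f0p) * math.exp(-dt / p[ITAUF0])
            tf = p[ITAUF]
            tf0 = p[ITAUF0]
            ef = math.exp(-dt / tf)
            if abs(tf0 - tf) < 1e-12 * tf:
                fc = p[IF0T] + (fp - p[IF0T]) * ef \
                    + (p[IF0T] - f0p) * (dt / tf) * ef
            else:
                ef0 = math.exp(-dt / tf0)
                fc = p[IF0T] + (fp - p[IF0T]) * ef \
                    - (p[IF0T] - f0p) * (tf0 / (tf0 - tf)) * (ef0 - ef)
        else:
            fc = f0c - (f0c - fp) * math.exp(-dt / p[ITAUF])
        if d_active:
            dc = 1.0 - (1.0 - dp) * math.exp(-dt / p[ITAUD])
        else:
            dc = 1.0
        if g_dyn:
            gc = gp * math.exp(-dt / p[ITAUG])
    return ll


@njit(cache=True)
def _log_prior_one(x, code, h1, h2):
    # 0: exponential(scale=h1); 1: beta(h1, h2); 2: uniform(h1, h2)
    if code == 0:
        if x <= 0.0:
            return -np.inf
        return -x / h1 - math.log(h1)
    if code == 1:
        if x <= 0.0 or x >= 1.0:
            return -np.inf
        lb = math.lgamma(h1) + math.lgamma(h2) - math.lgamma(h1 + h2)
        return (h1 - 1.0) * math.log(x) + (h2 - 1.0) * math.log(1.0 - x) - lb
    if x < h1 or x > h2:
        return -np.inf
    return -math.log(h2 - h1)


@njit(cache=True)
def _log_prior(theta, codes, h1, h2):
    lp = 0.0
    for k in range(theta.shape[0]):
        v = _log_prior_one(theta[k], codes[k], h1[k], h2[k])
        if v == -np.inf:
            return -np.inf
        lp += v
    return lp


@njit(cache=True)
def mh_sample_stp(times, y, pfull, free_idx,
                  f_exp, d_active, a_dyn, f0_dyn, g_dyn,
                  drive, noise_scale, sd_floor, noise_mode,
                  codes, h1, h2,
                  theta0, step0,
                  n_keep, n_burn, thin, seed):
    """Component-wise adaptive random-walk Metropolis-Hastings.

    One "step" is a full sweep over the free parameters. Proposal scales
    adapt towards 20-40% acceptance during burn-in only, then freeze so
    the kept chain targets the exact posterior. Returns the kept chain,
    per-sample log-likelihood and log-posterior, the post-burn-in
    acceptance rate and the final proposal scales.
    """
    np.random.seed(seed)
    k = free_idx.shape[0]
    p = pfull.copy()
    theta = theta0.copy()
    step = step0.copy()
    for j in range(k):
        p[free_idx[j]] = theta[j]
    ll = stp_loglik(times, y, p, f_exp, d_active, a_dyn, f0_dyn, g_dyn,
                    drive, noise_scale, sd_floor, noise_mode)
    lp = _log_prior(theta, codes, h1, h2)
    lpost = ll + lp

    chain = np.empty((n_keep, k))
    lls = np.empty(n_keep)
    lposts = np.empty(n_keep)

    acc_win = np.zeros(k)
    prop_win = np.zeros(k)
    n_acc_keep = 0.0
    n_prop_keep = 0.0

    total = n_burn + n_keep * thin
    kept = 0
    for it in range(total):
        for j in range(k):
            old = theta[j]
            theta[j] = old + step[j] * np.random.normal()
            lp_new = _log_prior(theta, codes, h1, h2)
            if lp_new == -np.inf:
                theta[j] = old
                prop_win[j] += 1.0
                if it >= n_burn:
                    n_prop_keep += 1.0
                continue
            p[free_idx[j]] = theta[j]
            ll_new = stp_loglik(times, y, p, f_exp, d_active, a_dyn,
                                f0_dyn, g_dyn, drive, noise_scale, sd_floor,
                                noise_mode)
            lpost_new = ll_new + lp_new
            prop_win[j] += 1.0
            if it >= n_burn:
                n_prop_keep += 1.0
            if math.log(np.random.random() + 1e-300) < lpost_new - lpost:
                lpost = lpost_new
                ll = ll_new
                acc_win[j] += 1.0
                if it >= n_burn:
                    n_acc_keep += 1.0
            else:
                theta[j] = old
                p[free_idx[j]] = old
        if it < n_burn:
            if (it + 1) % 200 == 0:
                for j in range(k):
                    if prop_win[j] > 0:
                        r = acc_win[j] / prop_win[j]
                        if r > 0.4:
                            step[j] *= 1.3
                        elif r < 0.2:
                            step[j] /= 1.3
                    acc_win[j] = 0.0
                    prop_win[j] = 0.0
        else:
            if (it - n_burn) % thin == 0:
                for j in range(k):
                    chain[kept, j] = theta[j]
                lls[kept] = ll
                lposts[kept] = lpost
                kept += 1
    acc_rate = n_acc_keep / n_prop_keep if n_prop_keep > 0 else 0.0
    return chain, lls, lposts, acc_rate, step


# ---------------------------------------------------------------------------
# CA3 spiking network
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_ca3(dt, n_steps, nE, nI,
            pe, pi,                       # [Cm, k, a(1/ms), b, c, d, vr, vt, vpeak]
            v_rev_e, v_rev_i,
            g_ee, g_ei, g_ie, g_ii, w_fix, tau_ge, tau_gi, tau_gff,
            plastic, tau_stdp, tau_cut, tau_eta, tau_z, xi, inv_rho,
            eta_ie, z_ie, eta_order,
            wee, wie,                     # (nE,nE), (nI,nE) dimensionless in [0,1]
            mf_t, mf_fib, n_fib, memb_off, memb,
            g_mf, mf_f0, mf_a, mf_tauf,
            pp_t, pp_w,
            iext,
            snap_every, wee_snap, wie_snap,
            spike_t, spike_id):
    """Forward-Euler integration of the CA3 network (all times in ms).

    Adaptive quadratic-integrate-and-fire neurons, exponential synapses,
    symmetric rate-scaled STDP on EE and IE connections implemented with
    exponential spike traces. Returns (n_spikes, status); status 0 is
    success, 1 means the spike buffer overflowed, 2 a numerical blow-up.
    """
    n = nE + nI
    v = np.empty(n)
    u = np.zeros(n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    gff = np.zeros(nE)       # feed-forward (mossy/perforant) conductance
    x = np.zeros(n)          # STDP kernel trace, all neurons
    cx = np.zeros(n)         # pair-count trace (soft cutoff window)
    eta = np.zeros(nE)
    z = np.zeros(nE)
    spikers = np.empty(n, dtype=np.int64)
    now = np.zeros(n)        # 1.0 for neurons spiking in this step

    for i in range(nE):
        v[i] = pe[6]
    for i in range(nI):
        v[nE + i] = pi[6]

    mf_f = np.full(n_fib, mf_f0)
    mf_last = np.full(n_fib, -1.0e12)

    dec_ge = math.exp(-dt / tau_ge)
    dec_gi = math.exp(-dt / tau_gi)
    dec_ff = math.exp(-dt / tau_gff)
    dec_x = math.exp(-dt / tau_stdp)
    dec_cx = math.exp(-dt / tau_cut)
    dec_eta = math.exp(-dt / tau_eta)
    dec_z = math.exp(-dt / tau_z)

    imf = 0
    ipp = 0
    nmf = mf_t.shape[0]
    npp = pp_t.shape[0]
    nsp = 0
    max_spikes = spike_t.shape[0]
    isnap = 0

    for step in range(n_steps + 1):
        if step % snap_every == 0 and isnap < wee_snap.shape[0]:
            for a_ in range(nE):
                for b_ in range(nE):
                    wee_snap[isnap, a_, b_] = wee[a_, b_]
            for a_ in range(nI):
                for b_ in range(nE):
                    wie_snap[isnap, a_, b_] = wie[a_, b_]
            isnap += 1
        if step == n_steps:
            break
        t = step * dt

        # feed-forward mossy-fiber events (per-fiber f^2 facilitation)
        while imf < nmf and mf_t[imf] <= t:
            fib = mf_fib[imf]
            f_pre = mf_f0 + (mf_f[fib] - mf_f0) * math.exp(-(t - mf_last[fib]) / mf_tauf)
            inc = g_mf * f_pre * f_pre
            for q in range(memb_off[fib], memb_off[fib + 1]):
                gff[memb[q]] += inc
            mf_f[fib] = f_pre + mf_a * (1.0 - f_pre)
            mf_last[fib] = t
            imf += 1

        # perforant-path-like events: shared static drive to every E cell
        while ipp < npp and pp_t[ipp] <= t:
            for c in range(nE):
                gff[c] += pp_w
            ipp += 1

        # membrane integration
        nspk = 0
        for i in range(n):
            if i < nE:
                cm = pe[0]; kk = pe[1]; aa = pe[2]; bb = pe[3]
                vr = pe[6]; vt = pe[7]; vp = pe[8]
            else:
                cm = pi[0]; kk = pi[1]; aa = pi[2]; bb = pi[3]
                vr = pi[6]; vt = pi[7]; vp = pi[8]
            vi = v[i]
            g_exc = ge[i] + gff[i] if i < nE else ge[i]
            dv = (kk * (vi - vr) * (vi - vt) - u[i]
                  - g_exc * (vi - v_rev_e) - gi[i] * (vi - v_rev_i)
                  + iext[i]) / cm
            vi += dt * dv
            u[i] += dt * aa * (bb * (v[i] - vr) - u[i])
            v[i] = vi
            if vi >= vp:
                spikers[nspk] = i
                nspk += 1
            elif abs(vi) > 10.0 * abs(vp):
                return nsp, 2

        # spike handling: reset, record, propagate, plasticity.
        # Pair updates use x[j] + now[j] so exactly coincident pairs
        # (cells of one ensemble detonated by the same fiber pulse spike
        # in the same step) contribute the full Delta-t = 0 kernel.
        for s in range(nspk):
            now[spikers[s]] = 1.0
        if eta_order >= 1:
            # the triggering spike's own eta (and, for mode 1, z)
            # increment is visible to the pair updates it causes
            for s in range(nspk):
                i = spikers[s]
                if i < nE:
                    eta[i] += xi
                    if eta_order == 1:
                        z[i] += inv_rho
        for s in range(nspk):
            i = spikers[s]
            if i < nE:
                v[i] = pe[4]
                u[i] += pe[5]
            else:
                v[i] = pi[4]
                u[i] += pi[5]
            if nsp >= max_spikes:
                return nsp, 1
            spike_t[nsp] = t + dt
            spike_id[nsp] = i
            nsp += 1

            if i < nE:
                # recurrent excitation EE and EI
                for m in range(nE):
                    ge[m] += g_ee * wee[i, m]
                for q in range(nI):
                    ge[nE + q] += g_ei * w_fix
                if plastic:
                    # per-pair rule: each partner spike within the soft
                    # cutoff window contributes (kernel - z); partners
                    # with no recent spikes leave the weight untouched
                    ei = eta[i]
                    zi = z[i]
                    for j in range(nE):
                        if j == i:
                            continue
                        xj = x[j] + now[j]
                        cj = cx[j] + now[j]
                        if cj > 1.0:
                            cj = 1.0
                        # i as postsynaptic partner of j
                        wnew = wee[j, i] + ei * (xj - zi * cj)
                        if wnew < 0.0:
                            wnew = 0.0
                        elif wnew > 1.0:
                            wnew = 1.0
                        wee[j, i] = wnew
                        # i as presynaptic partner of j: pairs with j's
                        # earlier spikes via the traces; a coincident
                        # pair is credited once, at j's own event above
                        cj2 = cx[j] if cx[j] < 1.0 else 1.0
                        wnew = wee[i, j] + eta[j] * (x[j] - z[j] * cj2)
                        if wnew < 0.0:
                            wnew = 0.0
                        elif wnew > 1.0:
                            wnew = 1.0
                        wee[i, j] = wnew
                    for q in range(nI):
                        cq = cx[nE + q] + now[nE + q]
                        if cq > 1.0:
                            cq = 1.0
                        wnew = wie[q, i] + eta_ie * (
                            x[nE + q] + now[nE + q] - z_ie * cq)
                        if wnew < 0.0:
                            wnew = 0.0
                        elif wnew > 1.0:
                            wnew = 1.0
                        wie[q, i] = wnew
            else:
                qq = i - nE
                for m in range(nE):
                    gi[m] += g_ie * wie[qq, m]
                for r in range(nI):
                    gi[nE + r] += g_ii * w_fix
                if plastic:
                    for m in range(nE):
                        # coincident pair credited at m's spike; x[m] here
                        # carries only m's earlier spikes
                        cm = cx[m] if cx[m] < 1.0 else 1.0
                        wnew = wie[qq, m] + eta_ie * (x[m] - z_ie * cm)
                        if wnew < 0.0:
                            wnew = 0.0
                        elif wnew > 1.0:
                            wnew = 1.0
                        wie[qq, m] = wnew

        # trace increments after pair processing
        for s in range(nspk):
            i = spikers[s]
            now[i] = 0.0
            x[i] += 1.0
            cx[i] += 1.0
            if i < nE:
                if eta_order == 0:
                    eta[i] += xi
                if eta_order != 1:
                    z[i] += inv_rho

        # exponential decays
        for i in range(n):
            ge[i] *= dec_ge
            gi[i] *= dec_gi
            x[i] *= dec_x
            cx[i] *= dec_cx
        for i in range(nE):
            gff[i] *= dec_ff
        for i in range(nE):
            eta[i] *= dec_eta
            z[i] *= dec_z

    return nsp, 0
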