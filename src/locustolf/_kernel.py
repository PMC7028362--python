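"""Compiled inner loop of the antennal-lobe integrator.

Numerically identical to the pure-numpy loop in ``al_network.integrate_al``
(same exponential-Euler updates in the same order); tested for agreement.
The kernel advances one chunk of steps at a time so that input noise can be
drawn from a numpy Generator outside, and mutates the state arrays in
place.  Spikes are written into preallocated (ids, times) buffers.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def _vtrap(x, scale):
    if abs(x) < 1e-7 * scale:
        return scale - x / 2.0
    return x / (np.expm1(x / scale))


@njit(cache=True, fastmath=False)
def step_chunk(
    n_chunk,
    t0,
    dt,
    # PN state (in/out)
    v_pn, na_m, na_h, k_n_pn, a_m, a_h, o_ach, last_pn_spike,
    # LN state (in/out)
    v_ln, ca_m, ca_h, k_n_ln, ca_conc, kca_m, o_gaba, last_ln_spike,
    # weighted adjacency
    w_ln_pn, w_pn_pn, w_pn_ln, w_ln_ln,
    # input for this chunk: envelope (n_chunk,), amplitudes, noise (n_chunk, n)
    env, pn_amp, ln_amp, noise_pn, noise_ln, noise_frac,
    # PN params
    pn_cm_nf, pn_g_l, pn_e_l, pn_g_kl, pn_e_kl, pn_g_na, pn_e_na,
    pn_g_k, pn_e_k, pn_g_a, pn_e_a,
    # LN params
    ln_cm_nf, ln_g_l, ln_e_l, ln_g_kl, ln_e_kl, ln_g_k, ln_e_k,
    ln_g_ca, ln_e_ca, ln_g_kca, ln_e_kca, ln_a_ca, ln_area, ln_tau_ca, ln_ca_inf,
    # synapse params
    ach_alpha, ach_beta, ach_e, ach_a_t, ach_t_max,
    gaba_alpha, gaba_beta, gaba_e, gaba_v0, gaba_sigma,
    # spike detection
    pn_thr, ln_thr, pn_refrac, ln_refrac,
    # outputs
    lfp_out, spk_pn_id, spk_pn_t, spk_ln_id, spk_ln_t,
):
    n_pn = v_pn.shape[0]
    n_ln = v_ln.shape[0]
    n_spk_pn = 0
    n_spk_ln = 0
    for s in range(n_chunk):
        t = t0 + s * dt

        # --- PN gates
        for i in range(n_pn):
            v = v_pn[i]
            al = 0.32 * _vtrap(-(v + 42.0), 4.0)
            be = 0.28 * _vtrap(v + 15.0, 5.0)
            na_m[i] = al / (al + be) + (na_m[i] - al / (al + be)) * np.exp(-dt * (al + be))
            al = 0.128 * np.exp(-(38.0 + v) / 18.0)
            be = 4.0 / (1.0 + np.exp(-(15.0 + v) / 5.0))
            na_h[i] = al / (al + be) + (na_h[i] - al / (al + be)) * np.exp(-dt * (al + be))
            al = 0.02 * _vtrap(-(30.0 + v), 5.0)
            be = 0.5 * np.exp(-(35.0 + v) / 40.0)
            k_n_pn[i] = al / (al + be) + (k_n_pn[i] - al / (al + be)) * np.exp(
                -dt * (al + be)
            )
            xi = 1.0 / (1.0 + np.exp(-(v + 60.0) / 8.5))
            tau = 1.0 / (np.exp((v + 35.8) / 19.7) + np.exp(-(v + 79.7) / 12.7))
            a_m[i] = xi + (a_m[i] - xi) * np.exp(-dt / tau)
            xi = 1.0 / (1.0 + np.exp((v + 78.0) / 6.0))
            tau = 1.0 / (np.exp((v + 46.0) / 5.0) + np.exp(-(v + 238.4) / 37.45))
            a_h[i] = xi + (a_h[i] - xi) * np.exp(-dt / tau)
            # nACh transmitter pulse after each PN spike
            t_conc = ach_a_t if (t - last_pn_spike[i]) < ach_t_max else 0.0
            rate = ach_alpha * t_conc + ach_beta
            o_inf = ach_alpha * t_conc / rate
            o_ach[i] = o_inf + (o_ach[i] - o_inf) * np.exp(-rate * dt)

        # --- LN gates, calcium, GABA release
        for j in range(n_ln):
            v = v_ln[j]
            xi = 1.0 / (1.0 + np.exp(-(v + 20.0) / 6.5))
            ca_m[j] = xi + (ca_m[j] - xi) * np.exp(-dt / 1.5)
            xi = 1.0 / (1.0 + np.exp((v + 25.0) / 12.0))
            tau = 0.3 * np.exp((v - 40.0) / 13.0) + 0.002 * np.exp(-(v - 60.0) / 29.0)
            ca_h[j] = xi + (ca_h[j] - xi) * np.exp(-dt / tau)
            al = 0.02 * _vtrap(-(30.0 + v), 5.0)
            be = 0.5 * np.exp(-(35.0 + v) / 40.0)
            k_n_ln[j] = al / (al + be) + (k_n_ln[j] - al / (al + be)) * np.exp(
                -dt * (al + be)
            )
            i_ca = ln_g_ca * ca_m[j] * ca_m[j] * ca_h[j] * (v - ln_e_ca)
            i_density = i_ca * 1e-3 / ln_area
            target = ln_ca_inf - ln_a_ca * ln_tau_ca * i_density
            ca_conc[j] = target + (ca_conc[j] - target) * np.exp(-dt / ln_tau_ca)
            if ca_conc[j] < 1e-12:
                ca_conc[j] = 1e-12
            xi = ca_conc[j] / (ca_conc[j] + 2.0)
            tau = 100.0 / (ca_conc[j] + 2.0)
            kca_m[j] = xi + (kca_m[j] - xi) * np.exp(-dt / tau)
            t_conc = 1.0 / (1.0 + np.exp(-(v - gaba_v0) / gaba_sigma))
            rate = gaba_alpha * t_conc + gaba_beta
            o_inf = gaba_alpha * t_conc / rate
            o_gaba[j] = o_inf + (o_gaba[j] - o_inf) * np.exp(-rate * dt)

        # --- synaptic conductances onto each population
        g_gaba_pn = np.dot(w_ln_pn, o_gaba)
        g_ach_pn = np.dot(w_pn_pn, o_ach)
        g_ach_ln = np.dot(w_pn_ln, o_ach)
        g_gaba_ln = np.dot(w_ln_ln, o_gaba)

        # --- PN membrane update + spike detection
        lfp_acc = 0.0
        for i in range(n_pn):
            v = v_pn[i]
            g_na_eff = pn_g_na * na_m[i] ** 3 * na_h[i]
            g_k_eff = pn_g_k * k_n_pn[i] ** 4
            g_a_eff = pn_g_a * a_m[i] ** 4 * a_h[i]
            i_ext = pn_amp[i] * env[s]
            if noise_frac > 0.0:
                i_ext *= 1.0 + noise_frac * noise_pn[s, i]
            g_tot = pn_g_l + pn_g_kl + g_na_eff + g_k_eff + g_a_eff + g_gaba_pn[i] + g_ach_pn[i]
            i_rev = (
                pn_g_l * pn_e_l
                + pn_g_kl * pn_e_kl
                + g_na_eff * pn_e_na
                + g_k_eff * pn_e_k
                + g_a_eff * pn_e_a
                + g_gaba_pn[i] * gaba_e
                + g_ach_pn[i] * ach_e
                + i_ext
            )
            v_inf = i_rev / g_tot
            v_new = v_inf + (v - v_inf) * np.exp(-dt * g_tot / pn_cm_nf)
            if v < pn_thr and v_new >= pn_thr and (t - last_pn_spike[i]) > pn_refrac:
                last_pn_spike[i] = t
                spk_pn_id[n_spk_pn] = i
                spk_pn_t[n_spk_pn] = t + dt
                n_spk_pn += 1
            v_pn[i] = v_new
            lfp_acc += v_new
        lfp_out[s] = lfp_acc / n_pn

        # --- LN membrane update + spikelet detection
        for j in range(n_ln):
            v = v_ln[j]
            g_ca_eff = ln_g_ca * ca_m[j] * ca_m[j] * ca_h[j]
            g_kca_eff = ln_g_kca * kca_m[j]
            g_k_eff = ln_g_k * k_n_ln[j] ** 4
            i_ext = ln_amp[j] * env[s]
            if noise_frac > 0.0:
                i_ext *= 1.0 + noise_frac * noise_ln[s, j]
            g_tot = ln_g_l + ln_g_kl + g_ca_eff + g_kca_eff + g_k_eff + g_gaba_ln[j] + g_ach_ln[j]
            i_rev = (
                ln_g_l * ln_e_l
                + ln_g_kl * ln_e_kl
                + g_ca_eff * ln_e_ca
                + g_kca_eff * ln_e_kca
                + g_k_eff * ln_e_k
                + g_gaba_ln[j] * gaba_e
                + g_ach_ln[j] * ach_e
                + i_ext
            )
            v_inf = i_rev / g_tot
            v_new = v_inf + (v - v_inf) * np.exp(-dt * g_tot / ln_cm_nf)
            if v < ln_thr and v_new >= ln_thr and (t - last_ln_spike[j]) > ln_refrac:
                last_ln_spike[j] = t
                spk_ln_id[n_spk_ln] = j
                spk_ln_t[n_spk_ln] = t + dt
                n_spk_ln += 1
            v_ln[j] = v_new

    return n_spk_pn, n_spk_ln
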