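"""Numba inner loop for the two-population network simulation.

All neurons of both populations live in one flat state array; edges
(intra- and inter-population) are stored in CSR layout with per-edge delays
expressed in integration steps.  Delayed spike delivery uses a ring buffer of
future conductance increments indexed by ``step mod buf_len``.

Voltage-dependent gating rates are evaluated through precomputed lookup
tables with linear interpolation (grid 0.02 mV), which keeps the per-step
cost low without altering the dynamics at the default step size; the exact
closed forms live in :mod:`ctcsim.model_core` and the tables are built from
them.

Integration is the Heun predictor–corrector scheme: an Euler predictor
followed by a trapezoidal corrector, applied to the membrane, gating and
conductance equations alike.  Synaptic and external spike increments are
applied at step boundaries.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# gating-table layout
V_TAB_MIN = -130.0
V_TAB_MAX = 80.0
V_TAB_DV = 0.02


def build_gating_tables():
    """Lookup tables (m_inf, alpha_n, beta_n, alpha_h, beta_h) on a dense V grid."""
    from . import model_core as mc

    v = np.arange(V_TAB_MIN, V_TAB_MAX + V_TAB_DV, V_TAB_DV)
    r = mc.gating_rates(v)
    minf = r.alpha_m / (r.alpha_m + r.beta_m)
    return np.ascontiguousarray(
        np.stack([minf, r.alpha_n, r.beta_n, r.alpha_h, r.beta_h]).astype(np.float64)
    )


@njit(cache=True, fastmath=True)
def _lookup(tab, V, inv_dv, n_tab):
    x = (V - V_TAB_MIN) * inv_dv
    if x < 0.0:
        x = 0.0
    elif x > n_tab - 2:
        x = n_tab - 2.0
    i = int(x)
    w = x - i
    minf = tab[0, i] * (1.0 - w) + tab[0, i + 1] * w
    an = tab[1, i] * (1.0 - w) + tab[1, i + 1] * w
    bn = tab[2, i] * (1.0 - w) + tab[2, i + 1] * w
    ah = tab[3, i] * (1.0 - w) + tab[3, i + 1] * w
    bh = tab[4, i] * (1.0 - w) + tab[4, i + 1] * w
    return minf, an, bn, ah, bh


@njit(cache=True, fastmath=True)
def run_network(
    # geometry
    n_total,  # total neuron count (both populations)
    n_a,  # neurons 0..n_a-1 are population A
    exc_mask,  # bool[n_total]
    # membrane (shared except capacitance)
    inv_Cm,  # float[n_total]
    g_Na, g_K, g_L, E_Na, E_K, E_L,
    tab,  # gating tables (5, n_tab)
    # synapse kinetics (two channels: 0 = exc/AMPA, 1 = inh/GABA_A)
    tau_d_e, tau_r_e, norm_e, E_e,
    tau_d_i, tau_r_i, norm_i, E_i,
    # edges, CSR over presynaptic neuron
    edge_ptr, edge_target, edge_delay, edge_weight, edge_is_inh,
    buf_len,
    # external drive
    rate_a, rate_b,  # shared OU traces, spikes/s per step
    w_ext,  # peak conductance per external spike
    ou_independent, ou_nu0, ou_sigma, ou_tau,
    stim_extra,  # float[n_total] additive rate (spikes/s), 0 for unstimulated
    stim_on, stim_off,  # step range
    # integration / recording
    dt, n_steps, record_stride, warmup_steps,
    v_thresh, refrac_steps,
    v_init,  # float[n_total] initial voltages
    n_init, h_init,
    seed,
    max_spikes,
):
    np.random.seed(seed)
    n_tab = tab.shape[1]
    inv_dv = 1.0 / V_TAB_DV

    V = v_init.copy()
    n_g = n_init.copy()
    h_g = h_init.copy()
    xd_e = np.zeros(n_total)
    xr_e = np.zeros(n_total)
    xd_i = np.zeros(n_total)
    xr_i = np.zeros(n_total)

    buf = np.zeros((buf_len, n_total, 2))

    ad_e = dt / tau_d_e
    ar_e = dt / tau_r_e
    ad_i = dt / tau_d_i
    ar_i = dt / tau_r_i
    # Heun update factor for dx/dt = -x/tau: 1 - a + a^2/2
    fd_e = 1.0 - ad_e + 0.5 * ad_e * ad_e
    fr_e = 1.0 - ar_e + 0.5 * ar_e * ar_e
    fd_i = 1.0 - ad_i + 0.5 * ad_i * ad_i
    fr_i = 1.0 - ar_i + 0.5 * ar_i * ar_i

    last_spike = np.full(n_total, -10 * refrac_steps, dtype=np.int64)
    spike_step = np.empty(max_spikes, dtype=np.int64)
    spike_neuron = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    overflow = False

    n_rec = (n_steps - warmup_steps) // record_stride
    ie_a = np.zeros(n_rec)
    ii_a = np.zeros(n_rec)
    ie_b = np.zeros(n_rec)
    ii_b = np.zeros(n_rec)
    v_probe = np.zeros(n_rec)
    acc_ie_a = 0.0
    acc_ii_a = 0.0
    acc_ie_b = 0.0
    acc_ii_b = 0.0
    n_exc_a = 0
    n_exc_b = 0
    for i in range(n_total):
        if exc_mask[i]:
            if i < n_a:
                n_exc_a += 1
            else:
                n_exc_b += 1

    # per-neuron OU states for the independent-drive mode
    nu_indep = np.empty(n_total)
    if ou_independent:
        for i in range(n_total):
            nu_indep[i] = ou_nu0 + ou_sigma * np.random.randn()
    ou_a = dt / ou_tau
    ou_amp = ou_sigma * np.sqrt(2.0 * dt / ou_tau)

    dt_s = dt * 1e-3  # step width in seconds, for rate -> probability

    err_neuron = -1
    err_step = -1

    for step in range(n_steps):
        slot = step % buf_len

        # deliver delayed increments scheduled for this step
        for i in range(n_total):
            we = buf[slot, i, 0]
            if we > 0.0:
                xd_e[i] += we * norm_e
                xr_e[i] += we * norm_e
                buf[slot, i, 0] = 0.0
            wi = buf[slot, i, 1]
            if wi > 0.0:
                xd_i[i] += wi * norm_i
                xr_i[i] += wi * norm_i
                buf[slot, i, 1] = 0.0

        # external Poisson drive (undelayed)
        in_window = stim_on <= step < stim_off
        ra = rate_a[step]
        rb = rate_b[step]
        for i in range(n_total):
            if ou_independent:
                xi = ou_amp * np.random.randn()
                x0 = nu_indep[i]
                pred = x0 - ou_a * (x0 - ou_nu0) + xi
                x0 = x0 - 0.5 * ou_a * ((x0 - ou_nu0) + (pred - ou_nu0)) + xi
                nu_indep[i] = x0
                r = x0 if x0 > 0.0 else 0.0
            else:
                r = ra if i < n_a else rb
            if in_window and stim_extra[i] > 0.0:
                r += stim_extra[i]
            if r > 0.0:
                if np.random.random() < r * dt_s:
                    xd_e[i] += w_ext * norm_e
                    xr_e[i] += w_ext * norm_e

        # Heun step for (V, n, h) with synaptic conductances
        rec = step >= warmup_steps
        sum_ie_a = 0.0
        sum_ii_a = 0.0
        sum_ie_b = 0.0
        sum_ii_b = 0.0

        for i in range(n_total):
            v0 = V[i]
            n0 = n_g[i]
            h0 = h_g[i]
            ge0 = xd_e[i] - xr_e[i]
            gi0 = xd_i[i] - xr_i[i]

            minf, an, bn, ah, bh = _lookup(tab, v0, inv_dv, n_tab)
            m3 = minf * minf * minf
            i_syn0 = ge0 * (E_e - v0) + gi0 * (E_i - v0)
            i_ion0 = (
                -g_Na * m3 * h0 * (v0 - E_Na)
                - g_K * n0 * n0 * n0 * n0 * (v0 - E_K)
                - g_L * (v0 - E_L)
            )
            fV0 = (i_ion0 + i_syn0) * inv_Cm[i]
            fn0 = an * (1.0 - n0) - bn * n0
            fh0 = ah * (1.0 - h0) - bh * h0

            v1 = v0 + dt * fV0
            n1 = n0 + dt * fn0
            h1 = h0 + dt * fh0
            ge1 = xd_e[i] * (1.0 - ad_e) - xr_e[i] * (1.0 - ar_e)
            gi1 = xd_i[i] * (1.0 - ad_i) - xr_i[i] * (1.0 - ar_i)

            minf, an, bn, ah, bh = _lookup(tab, v1, inv_dv, n_tab)
            m3 = minf * minf * minf
            i_syn1 = ge1 * (E_e - v1) + gi1 * (E_i - v1)
            i_ion1 = (
                -g_Na * m3 * h1 * (v1 - E_Na)
                - g_K * n1 * n1 * n1 * n1 * (v1 - E_K)
                - g_L * (v1 - E_L)
            )
            fV1 = (i_ion1 + i_syn1) * inv_Cm[i]
            fn1 = an * (1.0 - n1) - bn * n1
            fh1 = ah * (1.0 - h1) - bh * h1

            v_new = v0 + 0.5 * dt * (fV0 + fV1)
            n_new = n0 + 0.5 * dt * (fn0 + fn1)
            h_new = h0 + 0.5 * dt * (fh0 + fh1)
            if n_new < 0.0:
                n_new = 0.0
            elif n_new > 1.0:
                n_new = 1.0
            if h_new < 0.0:
                h_new = 0.0
            elif h_new > 1.0:
                h_new = 1.0

            if not (-130.0 < v_new < 80.0) or v_new != v_new:
                err_neuron = i
                err_step = step
                break

            # spike detection: upward crossing of threshold outside lockout
            if v0 < v_thresh <= v_new and step - last_spike[i] > refrac_steps:
                last_spike[i] = step
                if n_spikes < max_spikes:
                    spike_step[n_spikes] = step
                    spike_neuron[n_spikes] = i
                    n_spikes += 1
                else:
                    overflow = True
                # enqueue onto all outgoing edges
                for e in range(edge_ptr[i], edge_ptr[i + 1]):
                    tgt = edge_target[e]
                    ds = edge_delay[e]
                    sl = (step + ds) % buf_len
                    buf[sl, tgt, edge_is_inh[e]] += edge_weight[e]

            if rec:
                if exc_mask[i]:
                    abs_ie = ge0 * (E_e - v0)
                    if abs_ie < 0.0:
                        abs_ie = -abs_ie
                    abs_ii = gi0 * (E_i - v0)
                    if abs_ii < 0.0:
                        abs_ii = -abs_ii
                    if i < n_a:
                        sum_ie_a += abs_ie
                        sum_ii_a += abs_ii
                    else:
                        sum_ie_b += abs_ie
                        sum_ii_b += abs_ii

            V[i] = v_new
            n_g[i] = n_new
            h_g[i] = h_new

            # decay conductance states (Heun factor for pure decay)
            xd_e[i] *= fd_e
            xr_e[i] *= fr_e
            xd_i[i] *= fd_i
            xr_i[i] *= fr_i

        if err_neuron >= 0:
            break

        # accumulate per-step population means; write the average of each
        # record_stride-step window as one output sample (anti-aliased 1 kHz)
        if rec:
            k = step - warmup_steps
            ridx = k // record_stride
            if ridx < n_rec:
                acc_ie_a += sum_ie_a / n_exc_a
                acc_ii_a += sum_ii_a / n_exc_a
                acc_ie_b += sum_ie_b / n_exc_b
                acc_ii_b += sum_ii_b / n_exc_b
                if (k + 1) % record_stride == 0:
                    inv = 1.0 / record_stride
                    ie_a[ridx] = acc_ie_a * inv
                    ii_a[ridx] = acc_ii_a * inv
                    ie_b[ridx] = acc_ie_b * inv
                    ii_b[ridx] = acc_ii_b * inv
                    v_probe[ridx] = V[0]
                    acc_ie_a = 0.0
                    acc_ii_a = 0.0
                    acc_ie_b = 0.0
                    acc_ii_b = 0.0

    return (
        spike_step[:n_spikes],
        spike_neuron[:n_spikes],
        ie_a, ii_a, ie_b, ii_b,
        v_probe,
        overflow,
        err_neuron,
        err_step,
    )
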