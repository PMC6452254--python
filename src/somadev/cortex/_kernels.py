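"""Numba inner loop for the spiking cortical sheet.

Current-based LIF dynamics with one-step spike delay, exponential synaptic
filtering, Poisson background drive, inhomogeneous-Poisson channel input and
pair-based additive STDP on excitatory->excitatory (and channel->excitatory)
synapses.  All times are in milliseconds inside this module.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_network(
    # recurrent synapses (CSR by presynaptic neuron)
    indptr, post_idx, w, plastic,
    # incoming view: positions into w per postsynaptic neuron
    tindptr, tsyn, tpre,
    # input synapses (CSR by channel) and incoming view by post neuron
    in_indptr, in_post, in_w, in_plastic,
    tin_indptr, tin_syn, tin_ch,
    # drive
    rates, steps_per_frame, n_steps, dt,
    # state (mutated)
    v, refr, isyn, inbox, tr_pre, tr_post, tr_ch,
    # LIF parameters
    v_rest, v_th, v_reset, tau_m, t_ref_steps, tau_syn,
    # STDP parameters
    stdp_on, a_plus, a_minus, a_plus_in, a_minus_in,
    tau_plus, tau_minus, w_max, in_w_max,
    # background
    bg_rate, bg_w,
    seed,
    # outputs
    spike_counts, rec_nid, rec_t,
):
    np.random.seed(seed)
    n = v.shape[0]
    n_ch = in_indptr.shape[0] - 1
    d_syn = np.exp(-dt / tau_syn)
    p_bg = bg_rate * dt * 1e-3  # per-neuron array
    d_plus = np.exp(-dt / tau_plus)
    d_minus = np.exp(-dt / tau_minus)
    leak = dt / tau_m
    sum_v = 0.0
    dw_acc = 0.0
    n_rec = 0
    cap = rec_nid.shape[0]
    for step in range(n_steps):
        # deliver last step's spikes, decay synaptic drive and traces
        for i in range(n):
            isyn[i] = isyn[i] * d_syn + inbox[i]
            inbox[i] = 0.0
            tr_pre[i] *= d_plus
            tr_post[i] *= d_minus
        for c in range(n_ch):
            tr_ch[c] *= d_plus
        # channel input spikes (inhomogeneous Poisson)
        if n_ch > 0 and rates.shape[0] > 0:
            frame = step // steps_per_frame
            if frame >= rates.shape[0]:
                frame = rates.shape[0] - 1
            for c in range(n_ch):
                r = rates[frame, c]
                if r > 0.0 and np.random.random() < r * dt * 1e-3:
                    tr_ch[c] += 1.0
                    for s in range(in_indptr[c], in_indptr[c + 1]):
                        inbox[in_post[s]] += in_w[s]
                        if stdp_on and in_plastic[s]:
                            dw = a_minus_in * tr_post[in_post[s]]
                            nw = in_w[s] - dw
                            if nw < 0.0:
                                nw = 0.0
                            dw_acc += abs(in_w[s] - nw)
                            in_w[s] = nw
        # background Poisson drive
        for i in range(n):
            if p_bg[i] > 0.0 and np.random.random() < p_bg[i]:
                inbox[i] += bg_w
        # membrane update and threshold
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_reset
            else:
                v[i] += leak * (v_rest - v[i]) + dt * isyn[i]
            sum_v += v[i]
            if refr[i] == 0 and v[i] >= v_th:
                v[i] = v_reset
                refr[i] = t_ref_steps
                spike_counts[i] += 1
                if n_rec < cap:
                    rec_nid[n_rec] = i
                    rec_t[n_rec] = step * dt
                    n_rec += 1
                tr_pre[i] += 1.0
                tr_post[i] += 1.0
                # potentiate incoming plastic synapses (pre-before-post)
                if stdp_on:
                    for s in range(tindptr[i], tindptr[i + 1]):
                        sy = tsyn[s]
                        if plastic[sy]:
                            nw = w[sy] + a_plus * tr_pre[tpre[s]]
                            if nw > w_max:
                                nw = w_max
                            dw_acc += abs(nw - w[sy])
                            w[sy] = nw
                    for s in range(tin_indptr[i], tin_indptr[i + 1]):
                        sy = tin_syn[s]
                        if in_plastic[sy]:
                            nw = in_w[sy] + a_plus_in * tr_ch[tin_ch[s]]
                            if nw > in_w_max:
                                nw = in_w_max
                            dw_acc += abs(nw - in_w[sy])
                            in_w[sy] = nw
                # propagate and depress outgoing (post-before-pre)
                for s in range(indptr[i], indptr[i + 1]):
                    j = post_idx[s]
                    inbox[j] += w[s]
                    if stdp_on and plastic[s]:
                        nw = w[s] - a_minus * tr_post[j]
                        if nw < 0.0:
                            nw = 0.0
                        dw_acc += abs(w[s] - nw)
                        w[s] = nw
    return n_rec, sum_v, dw_acc
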