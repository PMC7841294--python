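"""Optional numba fast paths for the two hot simulation loops.

Semantics are identical to the pure-numpy implementations in ``snn`` and
``tripartite`` (same update ordering, same clipping); the jitted kernels only
reorder floating-point accumulations within a step.  If numba is unavailable
the package transparently falls back to the numpy paths; an equivalence test
pins the two backends against each other.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def present_kernel(raster, w, alive, theta, v, refrac, x_pre, x_post, counts,
                   dt, tau_mem, v_rest, v_reset, theta0, theta_plus, tau_theta,
                   delta_ref, w_max, w_recurrent, tau_trace, eta_pre, eta_post,
                   learning, use_astdp, w_alpha, sigma):
    """One mini-batch presentation (B replicas, T steps).

    Mutates ``w``, ``theta``, ``v``, ``refrac``, ``x_pre``, ``x_post`` and
    ``counts`` in place.
    """
    B, T, n_in = raster.shape
    n_out = w.shape[1]
    trace_decay = np.exp(-dt / tau_trace)
    theta_decay = np.exp(-dt / tau_theta)
    drive = np.zeros((B, n_out))
    spiked = np.zeros((B, n_out), dtype=np.bool_)
    prev_spiked = np.zeros((B, n_out), dtype=np.bool_)
    dw = np.zeros((n_in, n_out))

    for t in range(T):
        # synaptic drive: weighted input spikes + lateral inhibition from the
        # previous step's output spikes
        for b in range(B):
            tot_prev = 0.0
            for j in range(n_out):
                if prev_spiked[b, j]:
                    tot_prev += 1.0
            for j in range(n_out):
                inh = tot_prev
                if prev_spiked[b, j]:
                    inh -= 1.0
                drive[b, j] = w_recurrent * inh
            for i in range(n_in):
                if raster[b, t, i]:
                    for j in range(n_out):
                        drive[b, j] += w[i, j]

        # LIF integration, spike detection, reset, refractory
        n_spikes = 0.0
        for b in range(B):
            for j in range(n_out):
                if refrac[b, j] > 0.0:
                    v[b, j] = v_reset
                    refrac[b, j] = max(refrac[b, j] - dt, 0.0)
                    spiked[b, j] = False
                else:
                    v[b, j] = v[b, j] + (dt / tau_mem) * (v_rest - v[b, j]) \
                        + drive[b, j]
                    if v[b, j] >= theta0 + theta[j]:
                        spiked[b, j] = True
                        v[b, j] = v_reset
                        refrac[b, j] = delta_ref
                        counts[b, j] += 1.0
                        n_spikes += 1.0
                    else:
                        spiked[b, j] = False

        if learning:
            for j in range(n_out):
                theta[j] *= theta_decay
            for b in range(B):
                for j in range(n_out):
                    if spiked[b, j]:
                        theta[j] += theta_plus

        # traces: decay, then set spikers to exactly 1
        for b in range(B):
            for i in range(n_in):
                if raster[b, t, i]:
                    x_pre[b, i] = 1.0
                else:
                    x_pre[b, i] *= trace_decay
            for j in range(n_out):
                if spiked[b, j]:
                    x_post[b, j] = 1.0
                else:
                    x_post[b, j] *= trace_decay

        if learning:
            # batch-summed weight deltas using current-step traces; single
            # clip per step (matches the vectorized reference)
            touched = False
            for i in range(n_in):
                for j in range(n_out):
                    dw[i, j] = 0.0
            for b in range(B):
                for i in range(n_in):
                    if raster[b, t, i]:
                        touched = True
                        for j in range(n_out):
                            dw[i, j] -= eta_pre * x_post[b, j]
                for j in range(n_out):
                    if spiked[b, j]:
                        touched = True
                        for i in range(n_in):
                            factor = 1.0
                            if use_astdp:
                                factor = (w[i, j] / w_alpha) ** sigma
                            dw[i, j] += eta_post * x_pre[b, i] * factor
            if touched:
                for i in range(n_in):
                    for j in range(n_out):
                        if alive[i, j]:
                            nw = w[i, j] + dw[i, j]
                            if nw < 0.0:
                                nw = 0.0
                            elif nw > w_max:
                                nw = w_max
                            w[i, j] = nw
                        else:
                            w[i, j] = 0.0

        for b in range(B):
            for j in range(n_out):
                prev_spiked[b, j] = spiked[b, j]


@njit(cache=True)
def toy_kernel(u_pre, u_trans, pr0, faulty, pr, ag, v, refrac, astro,
               params, spike_out, dse_out, esp_out, pr_out, ca_out, ip3_out,
               glu_out, start_step, sample_stride):
    """Advance the toy tripartite simulation over one chunk of steps.

    ``astro`` packs the scalar astrocyte state
    [ca, ip3, h, glu, esp, ca_prev]; ``params`` packs the constants (see
    caller).  Recording arrays are written at sampling boundaries.
    """
    dt = params[0]
    tau_ag = params[1]
    r_ag = params[2]
    tau_glu = params[3]
    r_glu = params[4]
    tau_esp = params[5]
    m_esp = params[6]
    k_ag = params[7]
    ca_threshold = params[8]
    v1 = params[9]
    v2 = params[10]
    v3 = params[11]
    k3 = params[12]
    d1 = params[13]
    d2 = params[14]
    d3 = params[15]
    d5 = params[16]
    a2 = params[17]
    c0 = params[18]
    c1 = params[19]
    ip3_star = params[20]
    tau_ip3 = params[21]
    r_ip3 = params[22]
    p_pre = params[23]
    kick = params[24]
    tau_mem = params[25]
    v_rest = params[26]
    v_reset = params[27]
    theta0 = params[28]
    delta_ref = params[29]
    dt_ms = params[30]

    m, n_post, n_pre = u_pre.shape
    for k in range(m):
        t = start_step + k
        # pre spikes -> stochastic transmission -> suprathreshold kicks
        for i in range(n_post):
            n_trans = 0
            for s in range(n_pre):
                if u_pre[k, i, s] < p_pre and u_trans[k, i, s] < pr[i, s]:
                    n_trans += 1
            if refrac[i] > 0.0:
                v[i] = v_reset
                refrac[i] = max(refrac[i] - dt_ms, 0.0)
                spiked = False
            else:
                v[i] = v[i] + (dt_ms / tau_mem) * (v_rest - v[i]) + kick * n_trans
                spiked = v[i] >= theta0
                if spiked:
                    v[i] = v_reset
                    refrac[i] = delta_ref
            # 2-AG: decay + production per post-spike
            ag[i] = ag[i] + dt * (-ag[i] / tau_ag)
            if spiked:
                ag[i] += r_ag
                s_idx = t // sample_stride
                if s_idx < spike_out.shape[1]:
                    spike_out[i, s_idx] += 1.0

        ca, ip3, h, glu, esp, ca_prev = (astro[0], astro[1], astro[2],
                                         astro[3], astro[4], astro[5])
        ag_total = 0.0
        for i in range(n_post):
            ag_total += ag[i]
        # Li-Rinzel Ca2+/IP3/h dynamics
        ca_prev = ca
        m_inf = ip3 / (ip3 + d1)
        n_inf = ca / (ca + d5)
        free_er = c0 - (1.0 + c1) * ca
        j_chan = v1 * (m_inf * n_inf * h) ** 3 * free_er
        j_leak = v2 * free_er
        j_pump = v3 * ca * ca / (k3 * k3 + ca * ca)
        q2 = d2 * (ip3 + d1) / (ip3 + d3)
        dh = a2 * (q2 * (1.0 - h) - ca * h)
        dip3 = (ip3_star - ip3) / tau_ip3 + r_ip3 * ag_total
        ca = ca + dt * (j_chan + j_leak - j_pump)
        h = min(max(h + dt * dh, 0.0), 1.0)
        ip3 = ip3 + dt * dip3
        if ca < 0.0:
            ca = 0.0
        # gliotransmission: glutamate bolus per upward crossing; slow e-SP
        crossed = (ca_prev < ca_threshold) and (ca_threshold <= ca)
        glu = glu + dt * (-glu / tau_glu)
        if crossed:
            glu += r_glu
        esp = esp + (dt / tau_esp) * (-esp + m_esp * glu)
        astro[0], astro[1], astro[2] = ca, ip3, h
        astro[3], astro[4], astro[5] = glu, esp, ca_prev

        # release probabilities
        for i in range(n_post):
            dse_i = -ag[i] * k_ag
            for s in range(n_pre):
                if faulty[i, s]:
                    pr[i, s] = 0.0
                else:
                    p = pr0[i, s] + pr0[i, s] * (dse_i + esp) / 100.0
                    pr[i, s] = min(max(p, 0.0), 1.0)

        if (t + 1) % sample_stride == 0:
            s_idx = t // sample_stride
            if s_idx < esp_out.shape[0]:
                esp_out[s_idx] = esp
                ca_out[s_idx] = astro[0]
                ip3_out[s_idx] = astro[1]
                glu_out[s_idx] = glu
                for i in range(n_post):
                    dse_out[i, s_idx] = -ag[i] * k_ag
                    for s in range(n_pre):
                        pr_out[i, s, s_idx] = pr[i, s]
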