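"""Compiled inner loops for network simulation.

One step of the network advances, for every neuron, a pair of AMPA and a
pair of GABA filter variables (per postsynaptic neuron, since all synapses
onto a neuron share time constants; individual synaptic weights enter
through the impulse amplitude at spike delivery) and the three-variable
neuron state.  Spikes are delivered after a fixed latency through
pre-scaled delivery matrices: row ``j`` of ``WA``/``WG`` holds
``tau_m[post] * factor * J / tau_r`` for every target of source ``j``.

The fixed-point kernel mirrors the float kernel with int64 neuron state in
a Qm.f format and shift-add constant programs (see burstnet.fixedpoint);
synaptic filtering stays in float and the drive is quantized at the neuron
boundary each step, matching a datapath whose analog front end feeds a
digital neuron core.
"""

import numpy as np
from numba import njit

__all__ = ["run_network_float", "run_network_fixed"]


@njit(cache=False)
def run_network_float(n_steps, dt, raster, n_src, n_tot,
                      WA, WG,
                      tau_dA, tau_rA, tau_dG, tau_rG,
                      a, b, c, d, r, s, q, I_bias,
                      cbp, ca, cb, sbp, sa, sb,
                      x0, y0, z0, thr, refr_steps, delay_steps,
                      guard, drive_sat):
    """Integrate the network; writes neuron spikes into ``raster``.

    raster : (n_in + n_tot, n_steps) uint8, the first ``n_src - n_tot``...
    input rows prefilled; neuron k records at row ``n_in + k`` where
    ``n_in = n_src - (number of layer-2 neurons)`` — concretely the
    first n_src rows are the projection sources (inputs then layer 2)
    scanned for delivery, and rows n_in.. are written by the neurons.
    Returns 1 on numerical blow-up, else 0.
    """
    n_in = raster.shape[0] - n_tot
    x = np.full(n_tot, x0)
    y = np.full(n_tot, y0)
    z = np.full(n_tot, z0)
    I_A = np.zeros(n_tot)
    x_A = np.zeros(n_tot)
    I_G = np.zeros(n_tot)
    x_G = np.zeros(n_tot)
    last_spike = np.full(n_tot, -2**40, dtype=np.int64)

    for i in range(n_steps):
        # delayed spike delivery
        j_del = i - delay_steps
        if j_del >= 0:
            for src in range(n_src):
                if raster[src, j_del]:
                    for k in range(n_tot):
                        x_A[k] += WA[src, k]
                        x_G[k] += WG[src, k]
        # synaptic filters (impulses were added as exact jumps above)
        for k in range(n_tot):
            I_A[k] += dt * (x_A[k] - I_A[k]) / tau_dA
            x_A[k] += dt * (-x_A[k]) / tau_rA
            I_G[k] += dt * (x_G[k] - I_G[k]) / tau_dG
            x_G[k] += dt * (-x_G[k]) / tau_rG
        # neuron update (piecewise-linear HR)
        for k in range(n_tot):
            xk = x[k]
            i3 = np.searchsorted(cbp, xk, side="right")
            x3 = ca[i3] * xk + cb[i3]
            i2 = np.searchsorted(sbp, xk, side="right")
            x2 = sa[i2] * xk + sb[i2]
            I_net = I_A[k] - I_G[k]
            if I_net > drive_sat:
                I_net = drive_sat
            elif I_net < -drive_sat:
                I_net = -drive_sat
            I_net += I_bias
            dx = y[k] - a * x3 + b * x2 - z[k] + I_net
            dy = c - d * x2 - y[k]
            dz = r * (s * (xk - q) - z[k])
            x_new = xk + dt * dx
            y[k] += dt * dy
            z[k] += dt * dz
            if abs(x_new) > guard:
                return 1
            if x_new >= thr and xk < thr:
                if i - last_spike[k] >= refr_steps[k]:
                    raster[n_in + k, i] = 1
                    last_spike[k] = i
            x[k] = x_new
    return 0


@njit(cache=False)
def _prog_mul(v, shifts, signs, n_terms):
    """Multiplier-less constant product: sum of signed arithmetic shifts.

    Right shifts round half-up (an add of 2^(k-1) before the shift) to
    avoid the systematic floor bias that otherwise accumulates into
    spike-phase drift over long runs.
    """
    acc = np.int64(0)
    for t in range(n_terms):
        sh = shifts[t]
        if sh > 0:
            term = (v + (np.int64(1) << (sh - 1))) >> sh
        elif sh == 0:
            term = v
        else:
            term = v << (-sh)
        if signs[t] > 0:
            acc += term
        else:
            acc -= term
    return acc


@njit(cache=False)
def run_network_fixed(n_steps, dt, raster, n_src, n_tot,
                      WA, WG,
                      tau_dA, tau_rA, tau_dG, tau_rG,
                      cbp_q, sbp_q, cb_q, sb_q,
                      c_q, rsq_q,
                      ca_sh, ca_sg, ca_nt,
                      sa_sh, sa_sg, sa_nt,
                      b_sh, b_sg, b_nt,
                      d_sh, d_sg, d_nt,
                      rs_sh, rs_sg, rs_nt,
                      r_sh, r_sg, r_nt,
                      x0_q, y0_q, z0_q, thr_q, refr_steps, delay_steps,
                      frac_bits, dt_shift, sat_q, drive_sat):
    """Fixed-point twin of :func:`run_network_float`.

    Neuron state is int64 in Q(int).(frac_bits); all constant products are
    shift-add programs; dt multiplication is an arithmetic right shift.
    Synaptic drive is computed in float and quantized per step.
    Returns the number of saturation events (state clamped at +/- sat_q).
    """
    n_in = raster.shape[0] - n_tot
    scale = np.float64(2.0 ** frac_bits)
    x = np.full(n_tot, x0_q, dtype=np.int64)
    y = np.full(n_tot, y0_q, dtype=np.int64)
    z = np.full(n_tot, z0_q, dtype=np.int64)
    I_A = np.zeros(n_tot)
    x_A = np.zeros(n_tot)
    I_G = np.zeros(n_tot)
    x_G = np.zeros(n_tot)
    last_spike = np.full(n_tot, -2**40, dtype=np.int64)
    n_sat = 0
    half = np.int64(1) << (dt_shift - 1)

    for i in range(n_steps):
        j_del = i - delay_steps
        if j_del >= 0:
            for src in range(n_src):
                if raster[src, j_del]:
                    for k in range(n_tot):
                        x_A[k] += WA[src, k]
                        x_G[k] += WG[src, k]
        for k in range(n_tot):
            I_A[k] += dt * (x_A[k] - I_A[k]) / tau_dA
            x_A[k] += dt * (-x_A[k]) / tau_rA
            I_G[k] += dt * (x_G[k] - I_G[k]) / tau_dG
            x_G[k] += dt * (-x_G[k]) / tau_rG
        for k in range(n_tot):
            xk = x[k]
            i3 = np.searchsorted(cbp_q, xk, side="right")
            x3 = _prog_mul(xk, ca_sh[i3], ca_sg[i3], ca_nt[i3]) + cb_q[i3]
            i2 = np.searchsorted(sbp_q, xk, side="right")
            x2 = _prog_mul(xk, sa_sh[i2], sa_sg[i2], sa_nt[i2]) + sb_q[i2]
            I_net = I_A[k] - I_G[k]
            if I_net > drive_sat:
                I_net = drive_sat
            elif I_net < -drive_sat:
                I_net = -drive_sat
            I_q = np.int64(np.rint(I_net * scale))
            # dx = y - x3 + b*x2 - z + I   (a == 1 in this datapath)
            dx = (y[k] - x3 + _prog_mul(x2, b_sh[0], b_sg[0], b_nt[0])
                  - z[k] + I_q)
            # dy = c - d*x2 - y
            dy = c_q - _prog_mul(x2, d_sh[0], d_sg[0], d_nt[0]) - y[k]
            # dz = r*s*x - r*s*q - r*z
            dz = (_prog_mul(xk, rs_sh[0], rs_sg[0], rs_nt[0]) - rsq_q
                  - _prog_mul(z[k], r_sh[0], r_sg[0], r_nt[0]))
            x_new = xk + ((dx + half) >> dt_shift)
            y[k] += ((dy + half) >> dt_shift)
            z[k] += ((dz + half) >> dt_shift)
            if x_new > sat_q:
                x_new = sat_q
                n_sat += 1
            elif x_new < -sat_q:
                x_new = -sat_q
                n_sat += 1
            if x_new >= thr_q and xk < thr_q:
                if i - last_spike[k] >= refr_steps[k]:
                    raster[n_in + k, i] = 1
                    last_spike[k] = i
            x[k] = x_new
    return n_sat


@njit(cache=False)
def pairing_sums(pre_idx, post_idx, onsets_flat, offsets, isi_mean,
                 src_exc, post_inh, A_plus, A_minus, g_plus, g_minus, tau,
                 use_table, tbp, ta, tb):
    """All-to-all burst-pairing weight increments per connection.

    onsets_flat/offsets give each neuron's burst-onset times; connection k
    pairs every pre onset with every post onset, applies the adaptive
    learning rate (branch order by the source transmitter, 0.4 scale for
    interneuron targets) and the exponential (or piecewise-linear) decay
    of |IBI|.  The caller applies any dopamine gate afterwards.
    """
    n_conn = pre_idx.size
    dw = np.zeros(n_conn)
    for kc in range(n_conn):
        pre = pre_idx[kc]
        post = post_idx[kc]
        a0, a1 = offsets[pre], offsets[pre + 1]
        b0, b1 = offsets[post], offsets[post + 1]
        if a0 == a1 or b0 == b1:
            continue
        sig = isi_mean[post] - isi_mean[pre]
        acc = 0.0
        for ia in range(a0, a1):
            for ib in range(b0, b1):
                ibi = onsets_flat[ib] - onsets_flat[ia]
                if src_exc[kc]:
                    if ibi > 0:
                        rate = A_plus + sig / g_plus
                    else:
                        rate = A_minus + sig / g_minus
                else:
                    if ibi > 0:
                        rate = A_minus + sig / g_minus
                    else:
                        rate = A_plus + sig / g_plus
                if post_inh[kc]:
                    rate = 0.4 * rate
                lag = abs(ibi)
                if use_table:
                    it = np.searchsorted(tbp, lag, side="right")
                    decay = ta[it] * lag + tb[it]
                else:
                    decay = np.exp(-lag / tau)
                acc += rate * decay
        dw[kc] = acc
    return dw
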