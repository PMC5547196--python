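"""Compiled clock-driven integration kernels.

The network kernel advances all cells with a fixed time step using either
forward Euler or second-order Heun (explicit RK2).  Per step:

1. advance the OU conductance drive (exact transition, once per step,
   outside the RK2 stages);
2. accumulate per-target summed synaptic conductances from the per-source
   gating variables (per-source bookkeeping, mathematically identical to
   per-synapse gating for class-uniform parameters);
3. integrate the membrane equations (for Heun, synaptic and drive currents
   are recomputed at the second stage from the stage voltage with gating
   and OU conductance frozen at their step-start values);
4. update gating by the exact exponential branch solutions, using the
   transmitter state set by spikes of *previous* steps;
5. apply resets, record spikes, and start 1-ms transmitter pulses.

Spike times are recorded at the end time of the step in which V crossed
v_peak (no interpolation).  Gating is stored per presynaptic source per
projection; transmitter pulses saturate (overlapping pulses merge).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_SPIKE_OVERFLOW = 1
STATUS_BLOWUP = 2

_BLOWUP_MV = 1.0e3


@njit(cache=True)
def single_cell_euler(V0, u0, v_r, v_t, v_peak, a, b, c, d,
                      k_low, k_high, C_m, I_shift, I_const, dt, n_steps):
    """Forward-Euler single cell under constant current; returns spike times (ms)."""
    V = V0
    u = u0
    spikes = []
    for step in range(n_steps):
        k = k_low if V <= v_t else k_high
        dV = (k * (V - v_r) * (V - v_t) - u + I_shift + I_const) / C_m
        du = a * (b * (V - v_r) - u)
        V += dt * dV
        u += dt * du
        if V >= v_peak:
            V = c
            u += d
            spikes.append((step + 1) * dt)
    return np.array(spikes)


@njit(cache=True)
def network_kernel(
    dt, n_steps, integrator,
    v_r, v_t, v_peak, a, b, c, d, k_low, k_high, inv_Cm, I_shift,
    pop_id, n_pops, pop_size,
    V, u,
    I_tonic,
    ou_mask, ou_g, ou_mean, ou_decay, ou_sd_eff, ou_erev, noise_seed,
    proj_src_start, proj_n_src, proj_g, proj_is_exc,
    proj_e_on, proj_e_off, proj_s_inf,
    proj_indptr_off, flat_indptr, flat_targets, flat_s, proj_s_off,
    pulse_end, pulse_ms,
    e_exc, e_inh,
    rec_idx, rec_stride,
    spike_t, spike_i,
    mean_v, rec_exc, rec_inh,
):
    np.random.seed(noise_seed)
    n = V.shape[0]
    n_proj = proj_src_start.shape[0]
    cap = spike_t.shape[0]
    n_rec = rec_idx.shape[0]
    n_spikes = 0
    use_ou = ou_sd_eff >= 0.0  # sentinel: negative disables the OU branch

    A_exc = np.zeros(n)
    A_inh = np.zeros(n)

    # initial mean V (index 0)
    for i in range(n):
        mean_v[0, pop_id[i]] += V[i]
    for q in range(n_pops):
        mean_v[0, q] /= pop_size[q]

    for step in range(n_steps):
        t = step * dt
        t_next = t + dt

        # --- OU drive: exact transition, once per step
        if use_ou:
            for i in range(n):
                if ou_mask[i]:
                    g = ou_mean + (ou_g[i] - ou_mean) * ou_decay
                    if ou_sd_eff > 0.0:
                        g += ou_sd_eff * np.random.normal()
                    ou_g[i] = g

        # --- summed synaptic conductance per target
        for i in range(n):
            A_exc[i] = 0.0
            A_inh[i] = 0.0
        for p in range(n_proj):
            gmax = proj_g[p]
            soff = proj_s_off[p]
            ioff = proj_indptr_off[p]
            if proj_is_exc[p]:
                for j in range(proj_n_src[p]):
                    s = flat_s[soff + j]
                    if s > 1e-12:
                        gs = gmax * s
                        for e in range(flat_indptr[ioff + j], flat_indptr[ioff + j + 1]):
                            A_exc[flat_targets[e]] += gs
            else:
                for j in range(proj_n_src[p]):
                    s = flat_s[soff + j]
                    if s > 1e-12:
                        gs = gmax * s
                        for e in range(flat_indptr[ioff + j], flat_indptr[ioff + j + 1]):
                            A_inh[flat_targets[e]] += gs

        # --- record synaptic current traces (step-start values)
        if step % rec_stride == 0:
            r = step // rec_stride
            for m in range(n_rec):
                i = rec_idx[m]
                rec_exc[r, m] = A_exc[i] * (V[i] - e_exc)
                rec_inh[r, m] = A_inh[i] * (V[i] - e_inh)

        # --- integrate membrane equations
        for i in range(n):
            Vi = V[i]
            ui = u[i]
            Isyn = A_exc[i] * (Vi - e_exc) + A_inh[i] * (Vi - e_inh)
            Ioth = I_tonic[i]
            if use_ou and ou_mask[i]:
                Ioth -= ou_g[i] * (Vi - ou_erev)
            k = k_low[i] if Vi <= v_t[i] else k_high[i]
            dV0 = (k * (Vi - v_r[i]) * (Vi - v_t[i]) - ui + I_shift[i]
                   + Ioth - Isyn) * inv_Cm[i]
            du0 = a[i] * (b[i] * (Vi - v_r[i]) - ui)
            if integrator == 0:  # forward Euler
                V[i] = Vi + dt * dV0
                u[i] = ui + dt * du0
            else:  # Heun: predictor-corrector with currents re-evaluated
                V1 = Vi + dt * dV0
                u1 = ui + dt * du0
                Isyn1 = A_exc[i] * (V1 - e_exc) + A_inh[i] * (V1 - e_inh)
                Ioth1 = I_tonic[i]
                if use_ou and ou_mask[i]:
                    Ioth1 -= ou_g[i] * (V1 - ou_erev)
                k1 = k_low[i] if V1 <= v_t[i] else k_high[i]
                dV1 = (k1 * (V1 - v_r[i]) * (V1 - v_t[i]) - u1 + I_shift[i]
                       + Ioth1 - Isyn1) * inv_Cm[i]
                du1 = a[i] * (b[i] * (V1 - v_r[i]) - u1)
                V[i] = Vi + 0.5 * dt * (dV0 + dV1)
                u[i] = ui + 0.5 * dt * (du0 + du1)

        # --- gating update over [t, t+dt] from pulses of previous steps
        for p in range(n_proj):
            soff = proj_s_off[p]
            src0 = proj_src_start[p]
            e_on = proj_e_on[p]
            e_off = proj_e_off[p]
            s_inf = proj_s_inf[p]
            for j in range(proj_n_src[p]):
                s = flat_s[soff + j]
                if pulse_end[src0 + j] > t:
                    flat_s[soff + j] = s_inf + (s - s_inf) * e_on
                elif s > 0.0:
                    flat_s[soff + j] = s * e_off

        # --- resets, spike recording, transmitter pulse onset
        for i in range(n):
            Vi = V[i]
            if Vi >= v_peak[i]:
                V[i] = c[i]
                u[i] += d[i]
                if n_spikes >= cap:
                    return n_spikes, STATUS_SPIKE_OVERFLOW, step, i
                spike_t[n_spikes] = t_next
                spike_i[n_spikes] = i
                n_spikes += 1
                pulse_end[i] = t_next + pulse_ms
            elif np.abs(Vi) > _BLOWUP_MV:
                return n_spikes, STATUS_BLOWUP, step, i

        # --- population activity (post-reset mean V)
        for i in range(n):
            mean_v[step + 1, pop_id[i]] += V[i]
        for q in range(n_pops):
            mean_v[step + 1, q] /= pop_size[q]

    return n_spikes, STATUS_OK, -1, -1
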