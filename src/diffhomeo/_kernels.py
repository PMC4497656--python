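"""Numba inner loop of the spiking-network simulation.

One fused kernel advances membrane potentials (forward Euler, exact OU and
conductance decay), external Poisson arrivals (exponential waiting times),
recurrent spike propagation, optional additive nearest-neighbor STDP,
per-neuron Ca2+/nNOS chemistry, the NO field (FTCS diffusion-decay every
``steps_per_diff`` neuron steps) and the threshold update of the selected
homeostasis mode.

The chemistry and diffusion updates mirror :mod:`diffhomeo.chemistry`
exactly (decay-then-increment per step; deposit-then-FTCS per diffusion
step); equivalence is covered by tests.

Homeostasis modes: 0 off, 1 diffusive, 2 non-diffusive, 3 non-diffusive
with per-neuron targets, 4 combined diffusive + non-diffusive.
"""

import numpy as np
from numba import njit

NEVER = -1.0e18  # sentinel for "no previous spike"


@njit(cache=True)
def simulate_kernel(
    n_steps, dt, t0,
    # neuron parameters
    E_l, v_r, E_e, E_i, c_m, tau_m, tau_ref, tau_e, tau_i, tau_ou, sigma_ou,
    # neuron state (updated in place)
    v, ge, gi, gx, refrac, eta, theta,
    # chemistry state
    ca, nnos, no_local, no_diff,
    grid, grid_buf, cx, cy,
    # external drive
    seg_rates_ms, seg_len_steps, next_ext, i_const, J_ext,
    # connectivity
    indptr, targets, weights, is_exc,
    # chemistry parameters
    ca_spike, tau_ca, tau_nnos, hill_n, hill_k,
    r_diff, lam_ms, steps_per_diff, dt_diff,
    # homeostasis
    mode, tau_hip, no0_diff, no0_nd, no0_i, tau_d_comb, tau_nd_comb,
    # stdp
    stdp_on, A_plus, A_minus, tau_plus, tau_minus, g_max, g_min,
    ee_out_mask, in_indptr, in_sources, in_edge_id, last_spike, spike_buf,
    # recording
    bin_steps, rate_counts, snap_steps, theta_snap, no_snap,
    record_spikes, spike_t, spike_i,
    rng_seed,
):
    np.random.seed(rng_seed)
    n = v.shape[0]
    m = grid.shape[0]
    n_seg = seg_rates_ms.shape[0]

    # conductance currents: g[nS] * (E - v)[mV] / c_m[nF] is in mV/s; the
    # integration step runs in ms, hence the factor 1e-3
    c_inv = 1.0e-3 / c_m
    inv_tau_m = 1.0 / tau_m
    v_cand = np.empty(n)
    a_ou = np.exp(-dt / tau_ou)
    b_ou = np.sqrt(1.0 - a_ou * a_ou)
    dec_e = np.exp(-dt / tau_e)
    dec_i = np.exp(-dt / tau_i)
    dec_ca = np.exp(-dt / tau_ca)
    lam_dt = lam_ms * dt_diff
    hk_n = hill_k**hill_n
    spike_cap = spike_t.shape[0]
    n_bins = rate_counts.shape[0]
    n_snap = theta_snap.shape[0]

    spk_count = 0
    seg = 0
    seg_end = seg_len_steps

    for step in range(n_steps):
        t = t0 + step * dt
        # advance drive segment; Poisson is memoryless so waiting times are
        # simply resampled at the new rate
        if seg + 1 < n_seg and step >= seg_end:
            seg += 1
            seg_end += seg_len_steps
            for i in range(n):
                rs = seg_rates_ms[seg, i] * dt
                if rs > 0.0:
                    next_ext[i] = step - np.log(np.random.random()) / rs
                else:
                    next_ext[i] = np.inf

        # external Poisson arrivals (rare; exponential waiting times)
        for i in range(n):
            while next_ext[i] <= step:
                gx[i] += J_ext
                next_ext[i] += -np.log(np.random.random()) / (seg_rates_ms[seg, i] * dt)

        # branch-free decay / noise / candidate-voltage pass (SIMD-friendly),
        # then a branchy pass for refractoriness and spike detection.  Spike
        # propagation is deferred so increments act at the next step.
        noise = np.random.standard_normal(n)
        for i in range(n):
            ge[i] *= dec_e
            gi[i] *= dec_i
            gx[i] *= dec_e
            ca[i] *= dec_ca
            eta[i] = a_ou * eta[i] + b_ou * noise[i]
            vi = v[i]
            v_cand[i] = vi + dt * (
                (E_l - vi) * inv_tau_m
                + (ge[i] * (E_e - vi) + gi[i] * (E_i - vi) + gx[i] * (E_e - vi)) * c_inv
                + sigma_ou * eta[i]
                + i_const[i]
            )

        n_spk = 0
        b = step // bin_steps
        for i in range(n):
            if refrac[i] > 0.0:
                refrac[i] -= dt
                v[i] = v_r
            else:
                vi = v_cand[i]
                if vi >= theta[i]:
                    spike_buf[n_spk] = i
                    n_spk += 1
                    if b < n_bins:
                        rate_counts[b, i] += 1
                    if record_spikes and spk_count < spike_cap:
                        spike_t[spk_count] = t
                        spike_i[spk_count] = i
                    spk_count += 1
                    vi = v_r
                    refrac[i] = tau_ref
                    ca[i] += ca_spike
                v[i] = vi

        # spike effects: STDP pairing updates, then propagation
        for s in range(n_spk):
            i = spike_buf[s]
            if stdp_on and is_exc[i]:
                # i as postsynaptic: potentiate incoming E->E edges
                for kk in range(in_indptr[i], in_indptr[i + 1]):
                    src = in_sources[kk]
                    if is_exc[src] and last_spike[src] > NEVER * 0.5:
                        e = in_edge_id[kk]
                        w = weights[e] + A_plus * np.exp(
                            -(t - last_spike[src]) / tau_plus
                        ) * g_max
                        weights[e] = g_max if w > g_max else w
                # i as presynaptic: depress outgoing E->E edges (dt >= 0)
                for kk in range(indptr[i], indptr[i + 1]):
                    if ee_out_mask[kk] and last_spike[targets[kk]] > NEVER * 0.5:
                        w = weights[kk] - A_minus * np.exp(
                            -(t - last_spike[targets[kk]]) / tau_minus
                        ) * g_max
                        weights[kk] = g_min if w < g_min else w
            if is_exc[i]:
                for kk in range(indptr[i], indptr[i + 1]):
                    ge[targets[kk]] += weights[kk]
            else:
                for kk in range(indptr[i], indptr[i + 1]):
                    gi[targets[kk]] += weights[kk]
            last_spike[i] = t

        # chemistry (nNOS), NO field, intracellular NO, and homeostasis at
        # the diffusion step; nNOS is slow (tau = 100 ms), so relaxing it at
        # the 1 ms chemistry step is numerically indistinguishable from the
        # neuron step
        if (step + 1) % steps_per_diff == 0:
            for i in range(n):
                c3 = ca[i] ** hill_n
                nnos[i] += (c3 / (c3 + hk_n) - nnos[i]) * (dt_diff / tau_nnos)
                grid[cx[i], cy[i]] += nnos[i] * dt_diff
            for x in range(m):
                xm = m - 1 if x == 0 else x - 1
                xp = 0 if x == m - 1 else x + 1
                for y in range(m):
                    ym = m - 1 if y == 0 else y - 1
                    yp = 0 if y == m - 1 else y + 1
                    c = grid[x, y]
                    grid_buf[x, y] = c + r_diff * (
                        grid[xm, y] + grid[xp, y] + grid[x, ym] + grid[x, yp] - 4.0 * c
                    ) - lam_dt * c
            for x in range(m):
                for y in range(m):
                    grid[x, y] = grid_buf[x, y]
            for i in range(n):
                no_diff[i] = grid[cx[i], cy[i]]
                no_local[i] += dt_diff * (nnos[i] - lam_ms * no_local[i])

            if mode == 1:
                for i in range(n):
                    s = no_diff[i]
                    if s > 1e-12:
                        theta[i] += dt_diff / tau_hip * (s - no0_diff) / s
            elif mode == 2:
                for i in range(n):
                    s = no_local[i]
                    if s > 1e-12:
                        theta[i] += dt_diff / tau_hip * (s - no0_nd) / s
            elif mode == 3:
                for i in range(n):
                    s = no_local[i]
                    if s > 1e-12:
                        theta[i] += dt_diff / tau_hip * (s - no0_i[i]) / s
            elif mode == 4:
                for i in range(n):
                    s = no_diff[i]
                    if s > 1e-12:
                        theta[i] += dt_diff / tau_d_comb * (s - no0_diff) / s
                    s = no_local[i]
                    if s > 1e-12:
                        theta[i] += dt_diff / tau_nd_comb * (s - no0_nd) / s

        if (step + 1) % snap_steps == 0:
            k = (step + 1) // snap_steps - 1
            if k < n_snap:
                md = 0.0
                mn = 0.0
                for i in range(n):
                    theta_snap[k, i] = theta[i]
                    md += no_diff[i]
                    mn += no_local[i]
                no_snap[k, 0] = md / n
                no_snap[k, 1] = mn / n

    return spk_count


@njit(cache=True)
def white_noise_lif_rate(mu, sigma, theta, v_r, tau_m, dt, duration, seed):
    """Direct simulation oracle for the LIF transfer function.

    Integrates tau_m dV/dt = -V + mu + sigma*sqrt(tau_m)*xi(t) (white
    noise, no refractory period) by Euler-Maruyama with a Brownian-bridge
    correction for intra-step threshold crossings, which removes the
    O(sqrt(dt)) upward bias of the effective threshold.  Returns the
    empirical firing rate in Hz.  ``tau_m``, ``dt``, ``duration`` in
    seconds.
    """
    np.random.seed(seed)
    n_steps = int(duration / dt)
    amp = sigma * np.sqrt(dt / tau_m)
    var_step = amp * amp
    v = v_r
    count = 0
    chunk = 65536
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = np.random.standard_normal(m)
        for k in range(m):
            v_old = v
            v += dt * (mu - v) / tau_m + amp * noise[k]
            if v >= theta:
                v = v_r
                count += 1
            elif (theta - v_old) * (theta - v) < 16.0 * var_step:
                # prob. the bridge between v_old and v touched theta
                # (negligible, skipped, when both ends are >~ 5 step-sd away)
                p = np.exp(-2.0 * (theta - v_old) * (theta - v) / var_step)
                if np.random.random() < p:
                    v = v_r
                    count += 1
        done += m
    return count / duration
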