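"""Additive nearest-neighbor STDP on recurrent E->E synapses.

For each nearest-neighbor pair of pre- and postsynaptic spikes separated
by dt = t_pre - t_post the weight changes by

    dw = +A_plus  * exp(dt / tau_plus)  * g_max   if dt < 0  (pre before post)
    dw = -A_minus * exp(-dt / tau_minus) * g_max  if dt >= 0

with hard bounds g_min <= w <= g_max.  Depression is slightly stronger
than potentiation (A_minus > A_plus), which keeps uncorrelated-activity
drift negative and the weight distribution bimodal.  Pairing is
nearest-neighbor on each spike: every spike interacts with the most
recent spike of the partner neuron only.

The in-loop updates live in the simulation kernel; this module provides
the closed-form single-pair update (the reference the kernel is checked
against), an offline pairing walk-through for arbitrary spike trains, and
the shuffled-weight control.
"""

from __future__ import annotations

import numpy as np

from .connectivity import Connectivity
from .params import STDPParams


def pair_update(w: float, dt_ms: float, params: STDPParams) -> float:
    """Weight after a single nearest-neighbor pairing with lag dt = t_pre - t_post."""
    if dt_ms < 0:
        w = w + params.A_plus * np.exp(dt_ms / params.tau_plus) * params.g_max
    else:
        w = w - params.A_minus * np.exp(-dt_ms / params.tau_minus) * params.g_max
    return float(np.clip(w, params.g_min, params.g_max))


def apply_spike_trains(w0: float, pre_times, post_times, params: STDPParams) -> float:
    """Evolve a single synapse through two spike trains (offline reference).

    Replays the event sequence the simulator sees: at each postsynaptic
    spike the synapse pairs with the latest presynaptic spike
    (potentiation), and at each presynaptic spike with the latest
    postsynaptic spike (depression).
    """
    events = sorted(
        [(t, 0) for t in pre_times] + [(t, 1) for t in post_times]
    )
    w = w0
    last = [None, None]  # last pre, last post
    for t, kind in events:
        other = last[1 - kind]
        if other is not None:
            if kind == 1:  # postsynaptic spike: dt = t_pre - t_post < 0
                w = pair_update(w, other - t, params)
            else:          # presynaptic spike: dt = t_pre - t_post >= 0
                w = pair_update(w, t - other, params)
        last[kind] = t
    return w


def shuffle_weights(conn: Connectivity, seed=None, mask=None) -> np.ndarray:
    """Permute weight values across existing connections (degree-preserving).

    Only edges selected by ``mask`` (default: E->E edges) participate; the
    histogram of weights is invariant under the shuffle while per-neuron
    total input weights mix.  Returns the new weight array (the
    connectivity is not modified).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mask is None:
        mask = conn.ee_edge_mask()
    w = conn.weights.copy()
    idx = np.nonzero(mask)[0]
    w[idx] = w[idx[rng.permutation(len(idx))]]
    return w


def bound_fraction(weights, params: STDPParams, tol: float = 0.05) -> float:
    """Fraction of weights within ``tol`` * (g_max - g_min) of either bound."""
    w = np.asarray(weights, dtype=float)
    span = params.g_max - params.g_min
    return float(
        np.mean((w <= params.g_min + tol * span) | (w >= params.g_max - tol * span))
    )
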