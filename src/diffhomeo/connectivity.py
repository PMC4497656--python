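"""Sparse random connectivity on the unit torus.

Each ordered pair of neurons is connected independently with probability
epsilon = C/N (uniform networks), or epsilon * exp(-d^2 / 2 s^2) with d the
toroidal Euclidean distance (spatially restricted networks).  The first
0.8 N neurons are excitatory, the rest inhibitory; connection probability
is independent of type and autapses are excluded.  Neuron positions are
uniform random on the torus and independent of the adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Connectivity:
    """CSR adjacency (pre -> post) with per-edge conductance increments."""

    n: int
    n_exc: int
    indptr: np.ndarray        # (n+1,) int64, edges grouped by presynaptic neuron
    targets: np.ndarray       # (n_edges,) int32 postsynaptic indices
    weights: np.ndarray       # (n_edges,) float64 conductance increments (nS)
    positions: np.ndarray     # (n, 2) float64 on the unit torus
    is_exc: np.ndarray        # (n,) bool

    @property
    def n_edges(self) -> int:
        return len(self.targets)

    def out_edges(self, i: int):
        return slice(self.indptr[i], self.indptr[i + 1])

    def in_csr(self):
        """Reverse adjacency: for each post, the incoming edge ids and sources."""
        order = np.argsort(self.targets, kind="stable")
        sources = np.repeat(
            np.arange(self.n, dtype=np.int32), np.diff(self.indptr).astype(np.int64)
        )
        indptr_in = np.zeros(self.n + 1, dtype=np.int64)
        counts = np.bincount(self.targets, minlength=self.n)
        indptr_in[1:] = np.cumsum(counts)
        return indptr_in, sources[order], order.astype(np.int64)

    def mean_in_degree(self) -> float:
        return self.n_edges / self.n

    def ee_edge_mask(self) -> np.ndarray:
        """Edges whose pre- and post-synaptic neurons are both excitatory."""
        pre = np.repeat(np.arange(self.n), np.diff(self.indptr).astype(np.int64))
        return self.is_exc[pre] & self.is_exc[self.targets]


def toroidal_distance(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Euclidean distance on the unit torus between rows of p and q."""
    d = np.abs(p - q)
    d = np.minimum(d, 1.0 - d)
    return np.sqrt((d**2).sum(axis=-1))


def build_connectivity(
    n: int,
    C: float,
    seed=None,
    spatial_s: float | None = None,
    frac_exc: float = 0.8,
    J_e: float = 5.5,
    J_i: float = 64.0,
) -> Connectivity:
    """Sample the random graph and assign conductance increments by pre type."""
    if not 0 <= C < n:
        raise ValueError("require 0 <= C < n")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_exc = int(round(frac_exc * n))
    is_exc = np.zeros(n, dtype=bool)
    is_exc[:n_exc] = True
    positions = rng.random((n, 2))
    eps = C / n

    indptr = np.zeros(n + 1, dtype=np.int64)
    all_targets = []
    for pre in range(n):
        if spatial_s is None:
            p = np.full(n, eps)
        else:
            d = toroidal_distance(positions[pre], positions)
            p = eps * np.exp(-(d**2) / (2.0 * spatial_s**2))
        mask = rng.random(n) < p
        mask[pre] = False  # no autapses
        tgt = np.nonzero(mask)[0].astype(np.int32)
        all_targets.append(tgt)
        indptr[pre + 1] = indptr[pre] + len(tgt)
    targets = (
        np.concatenate(all_targets) if all_targets else np.empty(0, dtype=np.int32)
    )
    pre_exc = np.repeat(is_exc, np.diff(indptr).astype(np.int64))
    weights = np.where(pre_exc, J_e, J_i).astype(np.float64)
    return Connectivity(
        n=n, n_exc=n_exc, indptr=indptr, targets=targets,
        weights=weights, positions=positions, is_exc=is_exc,
    )
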