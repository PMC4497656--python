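"""NO signalling chemistry: Ca2+ influx, nNOS activation, and the NO field.

Each spike deposits a fixed Ca2+ increment which decays exponentially
(tau_Ca).  nNOS activation relaxes toward a Hill function of Ca2+ with
time constant tau_nNOS; the Hill form gives the sigmoidal Ca2+ dependence
of NO synthase.  Activated nNOS acts as a point source for NO, which
either diffuses on a periodic 2D grid with first-order decay (diffusive
signal) or accumulates intracellularly with the same decay (non-diffusive
signal).

These vectorized operations define the reference dynamics; the simulation
kernel implements the identical update rules in its inner loop (verified
by equivalence tests).
"""

from __future__ import annotations

import numpy as np

from .params import ChemParams


def update_calcium(ca: np.ndarray, spikes: np.ndarray, dt: float, params: ChemParams) -> np.ndarray:
    """Exponential decay with tau_Ca plus ca_spike per spike.

    ``spikes`` is a boolean mask or a count per neuron for this step.
    """
    return ca * np.exp(-dt / params.tau_ca) + params.ca_spike * np.asarray(spikes, dtype=float)


def hill(ca, n: float = 3.0, k: float = 1.0):
    """Sigmoidal nNOS activation curve, Ca^n / (Ca^n + K^n) in [0, 1)."""
    ca = np.asarray(ca, dtype=float)
    cn = ca**n
    return cn / (cn + k**n)


def update_nnos(nnos: np.ndarray, ca: np.ndarray, dt: float, params: ChemParams) -> np.ndarray:
    """First-order relaxation of nNOS activation toward Hill(Ca) with tau_nNOS."""
    target = hill(ca, params.hill_n, params.hill_k)
    return nnos + (target - nnos) * (dt / params.tau_nnos)


def update_no_nondiffusive(
    no_local: np.ndarray, nnos: np.ndarray, dt_ms: float, params: ChemParams
) -> np.ndarray:
    """Per-neuron ODE d[NO]/dt = [nNOS] - lambda [NO], no spatial coupling."""
    lam_ms = params.lambda_decay / 1000.0
    return no_local + dt_ms * (nnos - lam_ms * no_local)


def neuron_cells(positions: np.ndarray, params: ChemParams) -> np.ndarray:
    """Grid cell index (row-major flat) of each neuron on the torus."""
    m = params.n_side
    ij = np.floor(positions * m).astype(np.int64) % m
    return ij[:, 0] * m + ij[:, 1]


def deposit_sources(field: np.ndarray, cells: np.ndarray, nnos: np.ndarray, dt_ms: float) -> None:
    """Add [nNOS]_i * dt to each neuron's grid cell (point sources), in place."""
    np.add.at(field.reshape(-1), cells, nnos * dt_ms)


def step_diffusion(field: np.ndarray, params: ChemParams, dt_ms: float | None = None) -> np.ndarray:
    """One FTCS step of the diffusion-decay equation on the periodic grid.

    field' = field + r * (5-point Laplacian) - lambda*dt*field, with
    r = D*dt/ds^2.  Sources are deposited separately before this step.
    """
    dt = params.dt_diff if dt_ms is None else dt_ms
    r = (params.D / 1000.0) * dt / params.ds**2
    if r > 0.25 + 1e-12:
        raise ValueError("FTCS stability violated")
    lam_ms = params.lambda_decay / 1000.0
    lap = (
        np.roll(field, 1, axis=0) + np.roll(field, -1, axis=0)
        + np.roll(field, 1, axis=1) + np.roll(field, -1, axis=1)
        - 4.0 * field
    )
    return field + r * lap - lam_ms * dt * field


def sample_no(field: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Read the concentration of each neuron's grid cell."""
    return field.reshape(-1)[cells]
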