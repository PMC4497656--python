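"""Homeostatic threshold modulation and target calibration.

The firing threshold of each neuron integrates the relative error of its
NO read-out against a target concentration:

    d theta_i / dt = (1/tau_HIP) * ([NO]_i - [NO]_0) / [NO]_i

The same rule serves the diffusive and non-diffusive signals (only the NO
variable differs); the combined rule sums both terms with separate
timescales; the variable-target variant replaces the single target with
per-neuron targets sampled from a calibration network's steady-state NO
distribution.

The standalone updates here are the reference forms used by the tests;
the simulation kernel applies the identical update at the diffusion step
(1 ms), which is indistinguishable at the homeostatic timescale
(tau_HIP = 2500 ms) from updating at the neuron step.
"""

from __future__ import annotations

import numpy as np

from .inputs import draw_static_rates
from .network import Simulation


def update_thresholds(theta, no_signal, target, tau_hip_ms: float, dt_ms: float):
    """One Euler step of the relative-error threshold update.

    ``target`` may be a scalar or a per-neuron array.  Neurons whose NO
    signal is non-positive are skipped (startup transient before any NO
    has been synthesized).
    """
    theta = np.asarray(theta, dtype=float)
    no = np.asarray(no_signal, dtype=float)
    target = np.broadcast_to(np.asarray(target, dtype=float), no.shape)
    ok = no > 1e-12
    out = theta.copy()
    out[ok] += dt_ms / tau_hip_ms * (no[ok] - target[ok]) / no[ok]
    return out


def update_thresholds_combined(
    theta, no_diff, no_nondiff, target_diff, target_nondiff,
    tau_diffusive_ms: float, tau_nondiffusive_ms: float, dt_ms: float,
):
    """Combined rule: sum of the diffusive and non-diffusive relative errors."""
    theta = np.asarray(theta, dtype=float)
    nd = np.asarray(no_diff, dtype=float)
    nn = np.asarray(no_nondiff, dtype=float)
    out = theta.copy()
    ok = nd > 1e-12
    out[ok] += dt_ms / tau_diffusive_ms * (nd[ok] - target_diff) / nd[ok]
    ok = nn > 1e-12
    out[ok] += dt_ms / tau_nondiffusive_ms * (nn[ok] - target_nondiff) / nn[ok]
    return out


def calibrate_target(
    sim: Simulation, rate_hz: float = 5.0, duration_s: float = 100.0
) -> tuple[float, float]:
    """Run the network without homeostasis under uniform drive and set targets.

    All neurons receive ``rate_hz`` Poisson input for ``duration_s``; the
    diffusive target is the mean sampled NO concentration across neurons at
    the end of the run, and the non-diffusive target the mean intracellular
    concentration.  Both are stored on the simulation and returned.
    """
    if rate_hz <= 0:
        raise ValueError("calibration drive must be positive")
    rates = np.full(sim.n, float(rate_hz))
    sim.run(duration_s, rates, mode="off")
    no_d = float(sim.no_diff.mean())
    no_n = float(sim.no_local.mean())
    if no_d <= 0 or no_n <= 0:
        raise RuntimeError("calibration produced non-positive NO concentrations")
    sim.no0_diffusive = no_d
    sim.no0_nondiffusive = no_n
    return no_d, no_n


def draw_variable_targets(
    sim: Simulation,
    seed=None,
    mean_hz: float = 2.0,
    sd_hz: float = 5.0,
    duration_s: float = 100.0,
) -> np.ndarray:
    """Sample per-neuron homeostatic targets from a broad-input calibration run.

    The network runs without homeostasis under mu_i ~ N(mean, sd^2) Hz
    (clipped at 0); the steady-state intracellular NO concentrations form a
    broad, right-skewed distribution from which per-neuron targets are
    drawn with replacement.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        sim.seed + 1 if seed is None else seed
    )
    drive = draw_static_rates(sim.n, mean_hz, sd_hz, seed=rng)
    sim.run(duration_s, drive.rates, mode="off")
    pool = sim.no_local.copy()
    pool = pool[pool > 0]
    if len(pool) == 0:
        raise RuntimeError("calibration produced no positive NO concentrations")
    targets = rng.choice(pool, size=sim.n, replace=True)
    sim.no0_per_neuron = targets
    return targets
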