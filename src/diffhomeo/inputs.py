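"""External-input generators.

Every experiment drives the network with independent homogeneous Poisson
spike trains, one per neuron; the generators here produce the rate
structures the protocols assume: static Gaussian-distributed rates,
randomly chosen elevated-input groups, time-varying group offsets, and
orientation-tuned rates.

Rates drawn from a Gaussian can be negative; a Poisson process cannot, so
draws are clipped at 0 Hz.  The pre-clip values are retained on
:class:`ExternalDrive` for analyses that compare input changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExternalDrive:
    """Per-neuron external Poisson rates with optional group structure."""

    rates: np.ndarray                 # clipped rates (Hz), shape (n,)
    raw_rates: np.ndarray             # pre-clip Gaussian draws (Hz)
    group_labels: np.ndarray          # 0 = background, 1..k = groups
    seed: int | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if len(self.rates) != len(self.group_labels):
            raise ValueError("rates and group_labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.rates)

    def to_frame(self):
        """Columnar view (neuron_id, rate_hz, raw_rate_hz, group)."""
        import pandas as pd

        return pd.DataFrame({
            "neuron_id": np.arange(self.n),
            "rate_hz": self.rates,
            "raw_rate_hz": self.raw_rates,
            "group": self.group_labels,
        })


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_static_rates(n: int, mean: float, sd: float, seed=None) -> ExternalDrive:
    """Draw i.i.d. rates mu_i ~ N(mean, sd^2) Hz, clipped at 0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = _rng(seed)
    raw = rng.normal(mean, sd, size=n)
    return ExternalDrive(
        rates=np.clip(raw, 0.0, None),
        raw_rates=raw,
        group_labels=np.zeros(n, dtype=np.int64),
        seed=seed if isinstance(seed, int) else None,
    )


def assign_groups(n: int, group_sizes, seed=None, eligible=None) -> np.ndarray:
    """Randomly partition ``group_sizes`` disjoint groups out of ``eligible`` neurons.

    Returns integer labels of length ``n``: 0 for background, 1..k for groups.
    ``eligible`` restricts membership (e.g. to excitatory neurons); by default
    all neurons are eligible.  Group membership is independent of position.
    """
    group_sizes = list(group_sizes)
    if any(s < 0 for s in group_sizes):
        raise ValueError("group sizes must be non-negative")
    labels = np.zeros(n, dtype=np.int64)
    pool = np.arange(n) if eligible is None else np.asarray(eligible)
    if sum(group_sizes) > len(pool):
        raise ValueError(
            f"cannot place {sum(group_sizes)} neurons in {len(pool)} eligible slots"
        )
    rng = _rng(seed)
    chosen = rng.choice(pool, size=sum(group_sizes), replace=False)
    start = 0
    for g, size in enumerate(group_sizes, start=1):
        labels[chosen[start:start + size]] = g
        start += size
    return labels


@dataclass
class TimeVaryingPattern:
    """Group rate offsets, one independent N(0, sd^2) Hz draw per pattern step."""

    group_rates: np.ndarray   # (n_steps, n_groups) Hz, may be negative
    dt_pattern: float = 1.0   # seconds per pattern step
    sd: float = 25.0

    @property
    def duration(self) -> float:
        return self.group_rates.shape[0] * self.dt_pattern


def time_varying_pattern(
    n_groups: int, duration_s: float, sd: float = 25.0, dt_pattern: float = 1.0, seed=None
) -> TimeVaryingPattern:
    """Independent group offsets mu_{j,t} ~ N(0, sd^2) Hz, regenerated each step."""
    rng = _rng(seed)
    n_steps = int(round(duration_s / dt_pattern))
    offs = rng.normal(0.0, sd, size=(n_steps, n_groups)) if sd > 0 else np.zeros((n_steps, n_groups))
    return TimeVaryingPattern(group_rates=offs, dt_pattern=dt_pattern, sd=sd)


def pattern_drive(
    base_rates: np.ndarray, group_labels: np.ndarray, pattern: TimeVaryingPattern
) -> np.ndarray:
    """Total per-neuron rate segments: static rate + the neuron's group offset, clipped at 0.

    Returns an array of shape (n_steps, n) suitable for segmented simulation.
    Background neurons (label 0) keep their static rate.
    """
    n_steps, n_groups = pattern.group_rates.shape
    rates = np.tile(np.asarray(base_rates, dtype=float), (n_steps, 1))
    for g in range(1, n_groups + 1):
        mask = group_labels == g
        rates[:, mask] += pattern.group_rates[:, g - 1][:, None]
    return np.clip(rates, 0.0, None)


def circular_distance_deg(a, b, period: float = 360.0):
    """Signed minimal angular difference a - b mapped to (-period/2, period/2]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.where(d > period / 2, d - period, d)


@dataclass
class OrientationStimulus:
    """Gaussian orientation tuning of the external input rate."""

    preferred: np.ndarray     # per-neuron preferred orientation (deg)
    stimulus_angle: float     # theta_s (deg)
    base_rate: float = 20.0   # mu_b (Hz)
    amplitude: float = 2.5    # peak amplitude (Hz)
    width: float = 90.0       # sigma_s (deg)


def assign_preferred_orientations(n: int, seed=None) -> np.ndarray:
    """Uniform random preferred orientations in [0, 360) degrees."""
    return _rng(seed).uniform(0.0, 360.0, size=n)


def orientation_rates(stim: OrientationStimulus) -> ExternalDrive:
    """rate_i = mu_b + A * exp(-d(theta_s, theta_i)^2 / (2 sigma_s^2))."""
    d = circular_distance_deg(stim.preferred, stim.stimulus_angle)
    rates = stim.base_rate + stim.amplitude * np.exp(-(d**2) / (2.0 * stim.width**2))
    return ExternalDrive(
        rates=np.clip(rates, 0.0, None),
        raw_rates=rates.copy(),
        group_labels=np.zeros(len(rates), dtype=np.int64),
    )


def poisson_arrivals(rates, dt: float, duration: float, seed=None) -> np.ndarray:
    """Per-step Bernoulli realization of independent Poisson arrivals.

    ``dt`` and ``duration`` in seconds.  Returns a boolean (n_steps, n) array.
    Intended for small-scale checks; the simulator generates arrivals
    internally by exponential waiting times.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    rng = _rng(seed)
    n_steps = int(round(duration / dt))
    p = rates * dt
    return rng.random((n_steps, len(rates))) < p
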