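"""Derived statistics for the homeostasis experiments.

Rate-distribution summaries, linear-response R^2, SNR persistence time,
normalized RMS tracking error, population-vector orientation decoding,
and spike-train statistics (ISI, CV, autocorrelogram).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RateSummary:
    """Moments of a per-neuron mean-rate distribution over a window."""

    rates: np.ndarray
    window_s: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates))

    @property
    def variance(self) -> float:
        return float(np.var(self.rates))

    @property
    def skewness(self) -> float:
        return float(stats.skew(self.rates))

    def log_rates(self, floor_hz: float = 1e-2) -> np.ndarray:
        r = self.rates[self.rates > floor_hz]
        return np.log10(r)


def response_r2(dmu, dnu) -> float:
    """R^2 of the least-squares fit of rate changes against input changes."""
    dmu = np.asarray(dmu, dtype=float)
    dnu = np.asarray(dnu, dtype=float)
    if len(dmu) != len(dnu):
        raise ValueError("paired vectors required")
    if len(dmu) < 3:
        raise ValueError("need at least 3 points")
    if np.var(dmu) == 0:
        raise ValueError("zero variance in input changes: R^2 undefined")
    res = stats.linregress(dmu, dnu)
    return float(res.rvalue**2)


def smooth_uniform(series: np.ndarray, window_bins: int) -> np.ndarray:
    """Centered moving average along axis 0 (edges use partial windows)."""
    if window_bins <= 1:
        return np.asarray(series, dtype=float)
    kernel = np.ones(window_bins) / window_bins
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        norm = np.convolve(np.ones(len(series)), kernel, mode="same")
        return np.convolve(series, kernel, mode="same") / norm
    out = np.empty_like(series)
    norm = np.convolve(np.ones(series.shape[0]), kernel, mode="same")
    for j in range(series.shape[1]):
        out[:, j] = np.convolve(series[:, j], kernel, mode="same") / norm
    return out


def snr_series(rates_g1: np.ndarray, rates_g2: np.ndarray,
               bin_s: float = 1.0, smooth_s: float = 20.0) -> np.ndarray:
    """Signal-to-noise ratio (mu1 - mu2)/(sigma1 + sigma2) between two groups.

    ``rates_g1``/``rates_g2`` are (time, neurons) rate series; each
    neuron's series is smoothed with a uniform window before group means
    and standard deviations are taken across neurons.
    """
    if rates_g1.shape[1] == 0 or rates_g2.shape[1] == 0:
        raise ValueError("empty group")
    w = max(1, int(round(smooth_s / bin_s)))
    s1 = smooth_uniform(rates_g1, w)
    s2 = smooth_uniform(rates_g2, w)
    mu1, mu2 = s1.mean(axis=1), s2.mean(axis=1)
    sd1, sd2 = s1.std(axis=1), s2.std(axis=1)
    denom = sd1 + sd2
    denom[denom == 0] = np.finfo(float).tiny
    return (mu1 - mu2) / denom


def persistence_time(rates_g1: np.ndarray, rates_g2: np.ndarray,
                     bin_s: float = 1.0, smooth_s: float = 20.0,
                     onset_s: float = 0.0) -> float:
    """Time until the inter-group SNR first falls below zero.

    Returns the crossing time in seconds after ``onset_s``; ``inf`` if the
    SNR never crosses within the series (censored observation).
    """
    snr = snr_series(rates_g1, rates_g2, bin_s=bin_s, smooth_s=smooth_s)
    start = int(round(onset_s / bin_s))
    below = np.nonzero(snr[start:] < 0)[0]
    if len(below) == 0:
        return float("inf")
    return float(below[0] * bin_s)


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def tracking_rms(pattern: np.ndarray, response: np.ndarray) -> float:
    """RMS error between z-scored input pattern and z-scored response."""
    pattern = np.asarray(pattern, dtype=float)
    response = np.asarray(response, dtype=float)
    if pattern.shape != response.shape:
        raise ValueError("pattern and response must have equal length")
    return float(np.sqrt(np.mean((zscore(pattern) - zscore(response)) ** 2)))


def population_vector_decode(rates, preferred_deg) -> float:
    """Angle (deg, in [0, 360)) of the rate-weighted vector sum of preferred directions."""
    rates = np.asarray(rates, dtype=float)
    ang = np.deg2rad(np.asarray(preferred_deg, dtype=float))
    x = float(np.sum(rates * np.cos(ang)))
    y = float(np.sum(rates * np.sin(ang)))
    if np.hypot(x, y) < 1e-12:
        raise ValueError("zero population vector: decoded angle undefined")
    return float(np.rad2deg(np.arctan2(y, x)) % 360.0)


def circular_error_deg(decoded, stimulus) -> np.ndarray:
    """Signed circular difference decoded - stimulus mapped to (-180, 180]."""
    d = (np.asarray(decoded, dtype=float) - np.asarray(stimulus, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


@dataclass
class SpikeStatistics:
    isi_ms: np.ndarray          # pooled inter-spike intervals
    cv: np.ndarray              # per-neuron CV of ISIs (neurons with >= 2 ISIs)
    autocorr_lags_ms: np.ndarray
    autocorr: np.ndarray        # mean rate of coincident spikes per lag bin (Hz)


def spike_statistics(spike_t_s: np.ndarray, spike_i: np.ndarray, n: int,
                     duration_s: float, bin_ms: float = 2.5,
                     max_lag_ms: float = 100.0) -> SpikeStatistics:
    """ISI distribution, per-neuron CV, and the population-average autocorrelogram.

    The autocorrelogram is the average (across neurons) rate of coincident
    spikes in bins of ``bin_ms`` at each lag, with the zero-lag self-count
    removed.
    """
    spike_t_s = np.asarray(spike_t_s, dtype=float)
    spike_i = np.asarray(spike_i)
    isis = []
    cvs = []
    n_bins = int(round(duration_s * 1000.0 / bin_ms))
    t0 = spike_t_s.min() if len(spike_t_s) else 0.0
    counts = np.zeros((0,))
    max_lag_bins = int(round(max_lag_ms / bin_ms))
    acc = np.zeros(max_lag_bins + 1)
    n_used = 0
    for i in range(n):
        t = np.sort(spike_t_s[spike_i == i]) * 1000.0  # ms
        if len(t) >= 2:
            d = np.diff(t)
            isis.append(d)
            if d.mean() > 0:
                cvs.append(d.std() / d.mean())
        if len(t) >= 1 and n_bins > 0:
            idx = np.minimum(((t - t0 * 1000.0) / bin_ms).astype(int), n_bins - 1)
            c = np.bincount(idx, minlength=n_bins).astype(float)
            ac = np.correlate(c, c, mode="full")[n_bins - 1: n_bins + max_lag_bins]
            ac[0] -= len(t)  # remove zero-lag self-pairs
            acc += ac
            n_used += 1
    if n_used > 0:
        acc /= n_used * duration_s  # coincidences per second per neuron
    lags = np.arange(max_lag_bins + 1) * bin_ms
    return SpikeStatistics(
        isi_ms=np.concatenate(isis) if isis else np.empty(0),
        cv=np.asarray(cvs),
        autocorr_lags_ms=lags,
        autocorr=acc,
    )
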