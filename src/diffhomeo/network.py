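"""Conductance-based LIF recurrent network with NO signalling.

:class:`Simulation` owns the full mutable state (membrane potentials,
conductances, thresholds, chemistry, the NO grid) and advances it in
phases: a typical protocol is calibration (homeostasis off), a
homeostasis phase, freezing, and probe phases.  Successive :meth:`run`
calls continue from the current state, so experiment drivers compose
phases freely.  Every source of randomness derives from the constructor
seed; a given seed reproduces a protocol bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from ._kernels import NEVER, simulate_kernel
from .connectivity import Connectivity, build_connectivity
from .params import SimConfig

_MODE_CODE = {"off": 0, "diffusive": 1, "nondiffusive": 2, "variable_target": 3, "combined": 4}


@dataclass
class RunRecord:
    """Time series recorded during one :meth:`Simulation.run` call."""

    duration_s: float
    bin_s: float
    rates: np.ndarray           # (n_bins, n) firing rates in Hz
    theta: np.ndarray           # (n_snap, n) thresholds (mV), sampled each second
    no_mean: np.ndarray         # (n_snap, 2): mean diffusive / non-diffusive NO
    spike_count: int
    spike_t: np.ndarray | None = None   # seconds
    spike_i: np.ndarray | None = None

    def mean_rates(self, last_s: float | None = None) -> np.ndarray:
        """Per-neuron mean rate (Hz), optionally over the trailing window."""
        if last_s is None:
            return self.rates.mean(axis=0)
        k = max(1, int(round(last_s / self.bin_s)))
        return self.rates[-k:].mean(axis=0)

    def population_rate(self) -> np.ndarray:
        """Population-mean rate per time bin (Hz)."""
        return self.rates.mean(axis=1)


class Simulation:
    """A recurrent network plus its NO field, advanced phase by phase."""

    def __init__(self, config: SimConfig | None = None, seed: int | None = None,
                 connectivity: Connectivity | None = None):
        cfg = config if config is not None else SimConfig()
        self.cfg = cfg
        self.seed = cfg.seed if seed is None else int(seed)
        self._ss = np.random.SeedSequence(self.seed)
        self.rng = np.random.default_rng(self._ss.spawn(1)[0])
        self._kernel_seeds = iter(
            np.random.SeedSequence(self._ss.entropy, spawn_key=(999,)).generate_state(100000) >> 1
        )

        net = cfg.network
        if connectivity is None:
            connectivity = build_connectivity(
                net.n, net.C, seed=self.rng, spatial_s=net.spatial_s,
                frac_exc=net.frac_exc, J_e=net.J_e, J_i=net.J_i,
            )
        self.conn = connectivity
        self.n = connectivity.n
        self.is_exc = connectivity.is_exc

        m = cfg.chem.n_side
        ij = np.floor(connectivity.positions * m).astype(np.int64) % m
        self.cx, self.cy = ij[:, 0].copy(), ij[:, 1].copy()

        nrn = cfg.neuron
        self.v = self.rng.uniform(nrn.E_l, nrn.theta0, size=self.n)
        self.ge = np.zeros(self.n)
        self.gi = np.zeros(self.n)
        self.gx = np.zeros(self.n)
        self.refrac = np.zeros(self.n)
        self.eta = np.zeros(self.n)
        self.theta = np.full(self.n, nrn.theta0)
        self.ca = np.zeros(self.n)
        self.nnos = np.zeros(self.n)
        self.no_local = np.zeros(self.n)
        self.no_diff = np.zeros(self.n)
        self.grid = np.zeros((m, m))
        self._grid_buf = np.zeros((m, m))
        self.i_const = np.zeros(self.n)
        self.last_spike = np.full(self.n, NEVER)
        self.t_ms = 0.0

        # homeostatic targets; set by calibration (homeostasis module)
        self.no0_diffusive: float = np.nan
        self.no0_nondiffusive: float = np.nan
        self.no0_per_neuron: np.ndarray = np.full(self.n, np.nan)

        # STDP bookkeeping (reverse adjacency built lazily)
        self._in_csr = None

    def manifest(self) -> dict:
        """Resolved configuration and seed; sufficient to re-run bit-identically."""
        from dataclasses import asdict

        return {
            "seed": self.seed,
            "t_ms": self.t_ms,
            "neuron": asdict(self.cfg.neuron),
            "network": asdict(self.cfg.network),
            "chem": asdict(self.cfg.chem),
            "homeostasis": asdict(self.cfg.homeo),
            "stdp": asdict(self.cfg.stdp),
            "targets": {
                "diffusive": float(self.no0_diffusive),
                "nondiffusive": float(self.no0_nondiffusive),
                "per_neuron": bool(np.all(np.isfinite(self.no0_per_neuron))),
            },
        }

    # ------------------------------------------------------------------
    def _reverse_adjacency(self):
        if self._in_csr is None:
            self._in_csr = self.conn.in_csr() + (self.conn.ee_edge_mask(),)
        return self._in_csr

    def set_stdp_initial_weights(self) -> None:
        """Draw E->E weights from N(w0_mean, w0_sd^2) nS, clipped to the bounds."""
        p = self.cfg.stdp
        ee = self.conn.ee_edge_mask()
        w0 = self.rng.normal(p.w0_mean, p.w0_sd, size=int(ee.sum()))
        self.conn.weights[ee] = np.clip(w0, p.g_min, p.g_max)

    # ------------------------------------------------------------------
    def run(
        self,
        duration_s: float,
        rates_hz,
        mode: str | None = None,
        seg_len_s: float | None = None,
        stdp: bool = False,
        bin_s: float = 1.0,
        record_spikes: bool = False,
    ) -> RunRecord:
        """Advance the network ``duration_s`` seconds under the given drive.

        ``rates_hz`` is either a per-neuron vector (static drive) or an
        array of shape (n_segments, n) presented in order, each segment
        lasting ``seg_len_s`` seconds.  ``mode`` selects the homeostasis
        rule for this phase (default: the config's mode).
        """
        cfg = self.cfg
        nrn, chem, homeo = cfg.neuron, cfg.chem, cfg.homeo
        mode = homeo.mode if mode is None else mode
        if mode not in _MODE_CODE:
            raise ValueError(f"unknown homeostasis mode {mode!r}")
        code = _MODE_CODE[mode]
        if code in (1, 4) and not np.isfinite(self.no0_diffusive):
            raise RuntimeError("diffusive target not calibrated")
        if code in (2, 4) and not np.isfinite(self.no0_nondiffusive):
            raise RuntimeError("non-diffusive target not calibrated")
        if code == 3 and not np.all(np.isfinite(self.no0_per_neuron)):
            raise RuntimeError("per-neuron targets not set")

        rates = np.asarray(rates_hz, dtype=float)
        if rates.ndim == 1:
            rates = rates[None, :]
        if rates.shape[1] != self.n:
            raise ValueError("drive length must equal network size")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        seg_rates_ms = np.ascontiguousarray(rates / 1000.0)

        dt = nrn.dt
        n_steps = int(round(duration_s * 1000.0 / dt))
        if seg_len_s is None:
            seg_len_steps = max(n_steps, 1)
        else:
            seg_len_steps = int(round(seg_len_s * 1000.0 / dt))
        steps_per_diff = int(round(chem.dt_diff / dt))
        if abs(steps_per_diff * dt - chem.dt_diff) > 1e-9:
            raise ValueError("dt_diff must be a multiple of the neuron dt")

        kseed = int(next(self._kernel_seeds))
        # initial waiting times for the first segment
        r0 = seg_rates_ms[0] * dt
        with np.errstate(divide="ignore"):
            next_ext = np.where(
                r0 > 0, -np.log(self.rng.random(self.n)) / np.where(r0 > 0, r0, 1.0), np.inf
            )

        bin_steps = max(1, int(round(bin_s * 1000.0 / dt)))
        n_bins = max(1, -(-n_steps // bin_steps)) if n_steps > 0 else 1
        rate_counts = np.zeros((n_bins, self.n), dtype=np.int32)
        snap_steps = max(1, int(round(1000.0 / dt)))  # 1 s snapshots
        n_snap = max(1, n_steps // snap_steps) if n_steps > 0 else 1
        theta_snap = np.zeros((n_snap, self.n), dtype=np.float32)
        no_snap = np.zeros((n_snap, 2))

        if record_spikes:
            cap = int(self.n * duration_s * 60 + 10000)  # ~60 Hz headroom
            spike_t = np.empty(cap, dtype=np.float64)
            spike_i = np.empty(cap, dtype=np.int32)
        else:
            spike_t = np.empty(0, dtype=np.float64)
            spike_i = np.empty(0, dtype=np.int32)

        if stdp:
            in_indptr, in_sources, in_edge_id, ee_mask = self._reverse_adjacency()
        else:
            in_indptr = np.zeros(self.n + 1, dtype=np.int64)
            in_sources = np.empty(0, dtype=np.int32)
            in_edge_id = np.empty(0, dtype=np.int64)
            ee_mask = np.zeros(self.conn.n_edges, dtype=bool)

        sp = cfg.stdp
        no0_i = self.no0_per_neuron if code == 3 else np.zeros(self.n)

        if n_steps > 0:
            count = simulate_kernel(
                n_steps, dt, self.t_ms,
                nrn.E_l, nrn.v_r, nrn.E_e, nrn.E_i, nrn.c_m, nrn.tau_m, nrn.tau_ref,
                nrn.tau_e, nrn.tau_i, nrn.tau_ou, nrn.sigma_ou,
                self.v, self.ge, self.gi, self.gx, self.refrac, self.eta, self.theta,
                self.ca, self.nnos, self.no_local, self.no_diff,
                self.grid, self._grid_buf, self.cx, self.cy,
                seg_rates_ms, seg_len_steps, next_ext, self.i_const, cfg.network.J_ext,
                self.conn.indptr, self.conn.targets, self.conn.weights, self.is_exc,
                chem.ca_spike, chem.tau_ca, chem.tau_nnos, chem.hill_n, chem.hill_k,
                (chem.D / 1000.0) * chem.dt_diff / chem.ds**2,
                chem.lambda_decay / 1000.0, steps_per_diff, chem.dt_diff,
                code, homeo.tau_hip,
                float(self.no0_diffusive) if np.isfinite(self.no0_diffusive) else 0.0,
                float(self.no0_nondiffusive) if np.isfinite(self.no0_nondiffusive) else 0.0,
                np.asarray(no0_i, dtype=np.float64),
                homeo.tau_diffusive, homeo.tau_nondiffusive,
                stdp, sp.A_plus, sp.A_minus, sp.tau_plus, sp.tau_minus, sp.g_max, sp.g_min,
                ee_mask, in_indptr, in_sources, in_edge_id, self.last_spike,
                np.empty(self.n, dtype=np.int64),
                bin_steps, rate_counts, snap_steps, theta_snap, no_snap,
                record_spikes, spike_t, spike_i, kseed,
            )
        else:
            count = 0
        self.t_ms += n_steps * dt

        if not np.all(np.isfinite(self.v)):
            raise FloatingPointError("non-finite membrane potential: integration diverged")

        rec = RunRecord(
            duration_s=duration_s,
            bin_s=bin_steps * dt / 1000.0,
            rates=rate_counts / (bin_steps * dt / 1000.0),
            theta=theta_snap,
            no_mean=no_snap,
            spike_count=int(count),
        )
        if record_spikes:
            k = min(count, len(spike_t))
            rec.spike_t = spike_t[:k] / 1000.0
            rec.spike_i = spike_i[:k].copy()
        return rec
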