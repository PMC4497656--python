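"""Model parameter containers and defaults.

All defaults are the reference parameter set of the model: a conductance-based
LIF network with injected Ornstein-Uhlenbeck noise, per-neuron Ca2+/nNOS
chemistry, and an NO concentration field integrated on a periodic 2D grid.

Unit conventions
----------------
Voltages in mV, times in ms, conductances in nS, capacitance in nF
(nS/nF = 1/ms, so conductance currents divided by ``c_m`` are in mV/ms).
The diffusion coefficient ``D`` is given in um^2/s and the NO decay rate
``lambda_decay`` in 1/s; both are converted to ms-based units internally.
Chemical concentrations (Ca2+, nNOS, NO) are in arbitrary units -- only
ratios relative to the calibrated target enter the threshold update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class NeuronParams:
    """LIF neuron, synapse, and noise parameters."""

    E_l: float = -80.0        # leak reversal (mV)
    v_r: float = -60.0        # reset potential (mV)
    E_e: float = 0.0          # excitatory reversal (mV)
    E_i: float = -70.0        # inhibitory reversal (mV)
    c_m: float = 0.2          # membrane capacitance (nF)
    tau_m: float = 20.0       # membrane time constant (ms)
    tau_ref: float = 5.0      # absolute refractory period (ms)
    theta0: float = -50.0     # initial firing threshold (mV)
    tau_e: float = 3.0        # excitatory synaptic time constant (ms)
    tau_i: float = 7.0        # inhibitory synaptic time constant (ms)
    tau_ou: float = 1.0       # OU noise correlation time (ms)
    sigma_ou: float = 1.0     # OU noise amplitude (mV/ms drive on dv/dt)
    dt: float = 0.1           # integration step (ms)

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_ref", "tau_e", "tau_i", "tau_ou", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NetworkParams:
    """Population size and connectivity parameters."""

    n: int = 5000             # total neurons (0.8 N excitatory, 0.2 N inhibitory)
    frac_exc: float = 0.8
    C: float = 100.0          # mean synapses per neuron; epsilon = C/N
    J_e: float = 5.5          # excitatory conductance increment (nS)
    J_i: float = 64.0         # inhibitory conductance increment (nS)
    J_ext: float = 80.0       # external input conductance increment (nS)
    spatial_s: float | None = None  # Gaussian connectivity range (torus units); None = uniform

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.C < self.n:
            raise ValueError("require 0 <= C < n")


@dataclass
class ChemParams:
    """Ca2+/nNOS dynamics and the NO diffusion-decay field.

    The FTCS scheme for the 2D diffusion equation is stable when
    ``D*dt_diff/ds**2 <= 0.25``; violating configurations are rejected.
    """

    ca_spike: float = 1.0     # Ca2+ increment per spike (a.u.)
    tau_ca: float = 10.0      # Ca2+ decay (ms)
    tau_nnos: float = 100.0   # nNOS relaxation (ms)
    hill_n: float = 3.0       # Hill exponent
    hill_k: float = 1.0       # Hill half-activation
    D: float = 1000.0         # NO diffusion coefficient (um^2/s)
    lambda_decay: float = 0.1  # NO decay rate (1/s)
    grid_mm: float = 1.0      # side of the square tissue patch (mm)
    ds: float = 2.0           # grid spacing (um)
    dt_diff: float = 1.0      # diffusion / chemistry / homeostasis step (ms)

    @property
    def n_side(self) -> int:
        return int(round(self.grid_mm * 1000.0 / self.ds))

    @property
    def stability_number(self) -> float:
        # D in um^2/ms times dt_diff (ms) over ds^2 (um^2)
        return (self.D / 1000.0) * self.dt_diff / self.ds**2

    def __post_init__(self) -> None:
        if self.stability_number > 0.25 + 1e-12:
            raise ValueError(
                f"FTCS stability violated: D*dt/ds^2 = {self.stability_number:.3f} > 0.25"
            )


@dataclass
class HomeostasisParams:
    """Threshold-modulation parameters.

    ``mode`` selects which NO signal drives the relative-error update:
    ``"diffusive"`` samples the field at the neuron's grid cell,
    ``"nondiffusive"`` uses the purely intracellular concentration,
    ``"variable_target"`` is the non-diffusive rule with per-neuron targets,
    ``"combined"`` sums diffusive and non-diffusive terms with separate
    timescales, and ``"off"`` freezes thresholds.
    """

    mode: str = "off"
    tau_hip: float = 2500.0          # homeostasis timescale (ms)
    tau_diffusive: float = 2500.0    # combined mode: diffusive term (ms)
    tau_nondiffusive: float = 2500.0  # combined mode: non-diffusive term (ms)

    MODES = ("off", "diffusive", "nondiffusive", "variable_target", "combined")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"unknown homeostasis mode {self.mode!r}")
        for name in ("tau_hip", "tau_diffusive", "tau_nondiffusive"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class STDPParams:
    """Additive nearest-neighbor STDP on recurrent E->E synapses."""

    tau_plus: float = 20.0    # potentiation window (ms)
    tau_minus: float = 20.0   # depression window (ms)
    A_plus: float = 0.025
    A_minus: float = 0.0275   # depression slightly stronger than potentiation
    g_max: float = 10.0       # hard upper weight bound (nS)
    g_min: float = 0.0        # hard lower weight bound (nS)
    w0_mean: float = 7.5      # initial weight distribution N(7.5, 2.5^2) nS
    w0_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.g_max <= self.g_min:
            raise ValueError("g_max must exceed g_min")


@dataclass
class SimConfig:
    """Complete configuration for one simulated network."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    chem: ChemParams = field(default_factory=ChemParams)
    homeo: HomeostasisParams = field(default_factory=HomeostasisParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    seed: int = 0

    def scaled(self, n: int, ds: float = 10.0, grid_mm: float | None = None) -> "SimConfig":
        """Reduced-scale copy: ``n`` neurons on a smaller / coarser NO grid.

        Connectivity degree, conductances and all time constants are kept at
        their reference values so the balanced-state regime is preserved.
        Shrinking ``grid_mm`` together with ``n`` preserves the neuron
        density, and with it the ratio of a neuron's own point-source
        contribution to the shared NO background -- the quantity that sets
        how "diffusive" the diffusive signal is.
        """
        chem = replace(self.chem, ds=ds)
        if grid_mm is not None:
            chem = replace(chem, grid_mm=grid_mm)
        return replace(self, network=replace(self.network, n=n), chem=chem)


def stdp_config(n: int = 5000) -> SimConfig:
    """Reference configuration for plastic-synapse runs (J_ext = 40 nS, C = 250)."""
    cfg = SimConfig()
    cfg.network = replace(cfg.network, n=n, C=250.0, J_ext=40.0)
    return cfg
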