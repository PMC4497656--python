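# Methods

## Model overview

`diffhomeo` simulates homeostatic intrinsic plasticity (HIP) mediated by a
diffusive messenger (nitric oxide, NO) in a recurrent cortical network, and
contrasts it with canonical, purely cell-autonomous ("non-diffusive")
homeostasis.

The network is a conductance-based leaky integrate-and-fire (LIF) model:

    dv/dt = (E_l - v)/tau_m
            + [g_e (E_e - v) + g_i (E_i - v) + g_x (E_e - v)] / c_m
            + sigma_OU * eta(t)

with exponential synaptic conductances (tau_e = 3 ms excitatory and
external, tau_i = 7 ms inhibitory), increments J_e = 5.5 nS, J_i = 64 nS,
J_ext = 80 nS per presynaptic/external spike, and an Ornstein-Uhlenbeck
noise process eta (zero mean, unit variance, tau_OU = 1 ms).  A spike is
fired when v crosses the neuron's threshold theta_i; v resets to
v_r = -60 mV for tau_ref = 5 ms.  80% of the N neurons are excitatory;
each ordered pair is connected independently with probability C/N
(C = 100 synapses per neuron), inhibition scaled for a balanced state.
External input is an independent Poisson train per neuron.

Each spike adds a fixed Ca2+ increment which decays with tau_Ca = 10 ms.
nNOS activation relaxes with tau_nNOS = 100 ms toward a Hill function of
Ca2+ (n = 3, K = 1).  Activated nNOS is a point source for NO, which
either (i) diffuses on a periodic 2D grid (D = 1000 um^2/s) with
first-order decay lambda = 0.1 /s — the diffusive signal, sampled at each
neuron's grid cell — or (ii) accumulates intracellularly with the same
decay — the non-diffusive signal.  The threshold integrates the relative
error of the signal against a calibrated target [NO]_0:

    d theta_i / dt = (1/tau_HIP) ([NO]_i - [NO]_0) / [NO]_i,  tau_HIP = 2.5 s.

The target is calibrated by running the network for 100 s without
homeostasis under uniform 5 Hz drive and taking the mean NO concentration.
Variable-target homeostasis instead samples per-neuron targets (with
replacement) from the steady-state intracellular NO distribution of a
calibration network driven by mu_i ~ N(2, 5^2) Hz.  Combined homeostasis
sums diffusive and non-diffusive relative-error terms with separate
timescales.

## Interpretation choices in the governing equations

Several published forms of these equations are ambiguous or unit-
inconsistent as printed; the package resolves them as follows.

- **Synaptic currents and c_m.**  Conductance-based currents are divided
  by c_m = 0.2 nF so units close (nS * mV / nF = mV/s).  With this
  reading a single recurrent EPSP peaks below 1 mV, consistent with the
  balanced-state assumption.
- **nNOS dynamics.**  A pure integrator of the Hill term grows without
  bound; nNOS activation is therefore implemented as first-order
  relaxation toward the Hill function with time constant tau_nNOS — the
  only bounded reading consistent with the NO field reaching a steady
  state.
- **OU noise.**  sigma_OU * eta(t) is added directly to dv/dt with
  sigma_OU read as 1 mV/ms; eta uses the exact discrete OU update
  eta <- eta e^(-dt/tau) + sqrt(1 - e^(-2 dt/tau)) xi.
- **External events** enter as conductance increments J_ext on a channel
  with reversal E_e and decay tau_e (the same kinetics as recurrent
  excitation).

## Numerical scheme

- Forward Euler for the membrane at dt = 0.1 ms; conductance, Ca2+ and OU
  decays use exact exponential factors; spike transmission takes effect at
  the next integration step; no synaptic delays; autapses excluded.
- The NO field uses forward-time centered-space (FTCS) with the 5-point
  periodic Laplacian at dt_diff = 1 ms; stability requires
  D dt/ds^2 <= 0.25 and is validated at construction.  Sources deposit
  [nNOS]_i * dt into the neuron's grid cell before each step.  nNOS,
  intracellular NO and the thresholds are also updated at the 1 ms
  chemistry step — indistinguishable from updating at the neuron step
  given their 100 ms–2.5 s timescales.
- Homeostasis skips neurons whose NO signal is not yet positive (startup
  transient).  Thresholds are unbounded.
- External Poisson arrivals are generated by exponential waiting times
  (exact, and resampled on rate changes, valid by memorylessness).
- Every run derives all randomness from one seed (NumPy `SeedSequence`);
  identical seeds reproduce runs bit-for-bit.

## Mean-field reduction

A non-interacting population in reduced voltage units (v_r = 0,
theta_0 = 10) with the Ricciardi LIF transfer function

    phi(mu, sigma, theta) = [ sqrt(pi) tau_m
        int_{(v_r-mu)/sigma}^{(theta-mu)/sigma} e^{u^2} erfc(-u) du ]^{-1}

(no refractory term; tau_m = 20 ms), evaluated with 100-point
Gauss-Legendre quadrature on the scaled complementary error function
(overflow-safe; cross-checked against adaptive quadrature and against a
direct white-noise LIF simulation).  Inputs are mu_i ~ N(5.7, delta^2)
with sigma_i = sqrt(mu_i); recurrent self-consistency uses
mu = mu_ext + J C nu tau and sigma^2 = mu_ext + J^2 C nu tau, iterated
(damped) to 1e-4 Hz.  Homeostasis mixes local and global read-out:

    d theta_i/dt = (1/tau_HIP) [ (1-alpha)(phi_i - phi_0)/phi_i
                                 + alpha (phibar - phi_0)/phibar ]

Euler-stepped at 0.125 s with each relative-error term clipped to
[-5, 1] (the positive side is bounded by 1 analytically; the clip only
guards the phi -> 0 startup).  Default target phi_0 = 2 Hz.  The
correlated-population imitation draws (mu_i, theta_i) jointly Gaussian
with prescribed correlation.

The simulation oracle for the transfer function integrates the
white-noise LIF by Euler-Maruyama with a Brownian-bridge correction for
intra-step threshold crossings, removing the O(sqrt(dt)) threshold bias;
at dt = 20 us its residual bias is well below the 3% comparison band.

## Reduced-scale study conditions

Full-scale runs (N = 5000, 500x500 grid, hundreds to thousands of
simulated seconds per condition) take CPU-hours.  The desk-scale preset
used by the analysis scripts, the test suite, and `scripts/acceptance.py`
is chosen to preserve the mechanisms rather than the absolute numbers:

- **N = 640 neurons on a 0.36 x 0.36 mm patch** — the reference density
  of ~5000 neurons/mm^2.  Density matters because it sets the ratio of a
  neuron's own point-source contribution to the shared NO background,
  i.e. how non-local the diffusive signal is; C, all conductances and
  time constants keep their reference values so the balanced-state
  regime is unchanged.
- **Grid spacing ds = 5 um** (72x72), which keeps the self-cell
  singularity of the discrete point source at ~0.5% of the background,
  matching the reference discretization.
- **Homeostasis accelerated 5x**: tau_HIP -> 500 ms with lambda and D
  scaled up 5x.  This compresses every homeostatic transient five-fold
  while leaving the diffusive range sqrt(D/lambda) = 100 um — the
  spatial reach of the signal — unchanged.  (The reference parameters are
  themselves an acceleration of the ~15 min biological NO timescale,
  chosen on the same grounds.)
- Phase durations: 30 s calibration (12 NO decay constants), 60–100 s
  homeostasis (up to 200 tau_HIP; the reference protocol itself runs
  ~140 tau_HIP), 15–25 s measurement windows.
- Stimulated groups scale with the network: 5% of N per group (32 neurons
  at desk scale, matching 250 of 5000 at full scale), so the recurrent
  feedback from elevated groups keeps its reference weight.

At this scale the qualitative contrasts are preserved — broad vs narrow
rate distributions, persistence of input differences, response-linearity
and decoding orderings, bimodal STDP weights — and those orderings are
what the desk-scale tests assert.  Absolute magnitudes (e.g. printed
persistence times or R^2 values at N = 5000) are expected to differ;
diffusive-condition persistence typically exceeds the observation window
and is reported censored at it.  `Scale(accel=1)` with the default
configuration recovers the full-scale model.

What the synthetic inputs do not emulate: structured stimuli, spatially
organized input maps, temporal input correlations beyond the 1 s pattern
steps, and any dependence of input statistics on neuron position.
Passing tests therefore demonstrate properties of the homeostatic
mechanisms under statistically homogeneous drive, not performance on
naturalistic input.

## Analysis conventions

- Response linearity: after freezing homeostasis, inputs are redrawn
  from the original distribution; R^2 is from ordinary least squares of
  per-neuron rate changes on changes of the *delivered* (clipped at
  0 Hz) Poisson rates.
- Persistence: SNR = (mu_1 - mu_2)/(sigma_1 + sigma_2) between the two
  elevated groups' per-neuron smoothed rates (uniform window, 20 s at
  full scale, 4 s under 5x acceleration); persistence is the first
  SNR < 0 crossing, censored at the run end otherwise.
- Tracking: pattern and the group's rate deviation from the population
  mean are both z-scored over the evaluation window before the RMS
  error; z-scoring makes the error scale-free (identical series give 0,
  uncorrelated series sqrt(2), anticorrelated 2).
- Decoding: population vector over excitatory neurons' stimulus
  responses — trial rates minus each neuron's untuned-baseline rate,
  rectified at 0.  (At desk scale the untuned rate component, summed over
  randomly assigned preferred directions, would otherwise dominate the
  vector; at thousands of neurons it cancels and raw rates suffice.)
  Errors are signed circular differences in (-180, 180] and the spread
  is their standard deviation.  Inhibitory neurons receive the untuned
  base rate.
- Spike statistics: CV of ISIs per neuron (>= 2 ISIs required);
  autocorrelogram as the mean rate of coincident spikes in 2.5 ms bins
  with the zero-lag self-count removed.
- STDP pairing is nearest-neighbor on each spike: a spike interacts with
  the partner's most recent spike only; weight updates apply immediately
  and transmission uses the updated weight.  The weight histogram's
  "bound fraction" counts weights within 5% of either hard bound.

## Known limitations

- Forward Euler with threshold detection at step boundaries slightly
  delays spikes (sub-dt); the f-I curve test bounds this at < 2%.
- The FTCS point source has a discrete self-cell excess; the reduced
  preset keeps it at the reference level rather than removing it.
- Desk-scale group statistics (32 neurons per group) make SNR-, RMS- and
  decoder-based metrics noisy; comparisons are asserted as orderings, not
  magnitudes, and the tracking comparison uses medians over independent
  network realizations (single pairs sit within realization noise).
- The weight-dependent STDP variant, boundary conditions other than
  periodic, 3D diffusion, and vascular NO sinks are out of scope.
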