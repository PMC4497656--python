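# diffhomeo

Spiking-network and mean-field models of **diffusive homeostatic intrinsic
plasticity**: firing-threshold regulation driven by a volume-transmitted
messenger (nitric oxide) that mixes each neuron's activity with its
neighbors', contrasted with canonical cell-autonomous ("non-diffusive")
homeostasis.

## The scientific question

Homeostatic intrinsic plasticity (HIP) is usually modeled as a local
negative feedback: each neuron senses its own activity and adjusts its
excitability toward a target, which stabilizes network activity but also
erases the broad, heavy-tailed firing-rate heterogeneity seen in cortex.
NO, a gas synthesized on spiking via Ca2+ -> nNOS and diffusing freely
through tissue, provides a read-out that is part own-activity, part
population average.  This package implements both signal types in the same
network and asks what the diffusive read-out changes.

The model: a balanced conductance-based LIF network (80% excitatory,
connection probability C/N) with per-neuron Poisson input at rates
mu_i ~ N(10, 10^2) Hz.  Spikes drive Ca2+ influx; nNOS activation follows a
Hill function of Ca2+; NO either diffuses on a periodic 2D grid
(D = 1000 um^2/s, decay lambda = 0.1/s) or stays intracellular.  Each
threshold integrates the relative error against a calibrated target:

    d(theta_i)/dt = (1/tau_HIP) * ([NO]_i - [NO]_0) / [NO]_i

A dynamic mean-field reduction (Ricciardi transfer function, thresholds
driven by an alpha-mixture of own-rate and population-rate errors)
reproduces the mechanism analytically: alpha = 0 is non-diffusive,
alpha -> 1 a fully shared signal.

Headline contrasts the experiments measure: steady-state rate-distribution
variance (broad for diffusive, collapsed for non-diffusive), persistence of
elevated-input group differences, linearity (R^2) of the population
response to input redraws, tracking of time-varying inputs, orientation
decoding, and retention of these properties under additive E->E STDP.

## Layout

- `src/diffhomeo/` — the library: input generators, connectivity, the
  numba LIF + NO-field kernel, homeostasis rules, STDP, mean-field
  analysis, metrics, and the experiment protocols.
- `analysis/01_*.py ... 08_*.py` — numbered drivers reproducing each
  figure-level experiment at desk scale; each writes tidy CSV tables under
  `results/`.
- `docs/methods.md` — model equations, interpretation and numerical
  choices, and the reduced-scale study conditions.

## Worked example

The mean-field analysis captures the core effect in seconds:

    python analysis/07_meanfield.py --seed 1

prints (abridged):

     alpha  rate_mean  rate_variance     theta_sd
      0.00   2.000006   8.473127e-10 5.462615e-01
      0.50   2.000183   4.034695e-05 5.440110e-01
      0.80   2.002088   2.252098e-02 4.899338e-01
      0.95   2.004726   4.679566e-01 2.806651e-01
      1.00   1.999995   1.356689e+00 1.776357e-15
    ...
    group-difference decay rate: alpha=0 0.2800/s, alpha=0.95 0.01639/s, ratio 0.059 (expected ~ 1 - alpha)

Reading: in every case the population mean sits at the 2 Hz target, but a
purely local read-out (alpha = 0) forces each neuron there individually
(rate variance ~ 1e-9, thresholds spread to match each neuron's input),
while an increasingly global read-out leaves individual rates spread out
(variance 0.02 -> 1.36 Hz^2) with increasingly uniform thresholds.  Input
differences between stimulated groups decay at (1 - alpha) times the
local-read-out speed — the mechanism behind the spiking network's long
persistence times under diffusive homeostasis.

The spiking-network contrasts come from `analysis/01_...`:

    python analysis/01_steady_state_and_linearity.py --seed 1

which runs the three homeostatic conditions to steady state (N = 640,
accelerated-homeostasis desk scale; see `docs/methods.md`) and prints the
rate-distribution variance, response-linearity R^2, and the
population-rate jump after an input redraw per condition.

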