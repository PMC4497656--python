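"""Figure-level experiment protocols at configurable scale.

Each protocol composes the standard phases -- target calibration
(homeostasis off, uniform drive), a homeostasis phase under the
experiment's input ensemble, freezing, and probe phases -- and returns
the derived metrics.  Durations and sizes are explicit arguments so the
same code runs desk-scale checks and full-scale reproductions; reduced
scale preserves the balanced-state regime (connectivity degree,
conductances and all time constants keep their reference values).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

from . import inputs, metrics, stdp as stdp_mod
from .homeostasis import calibrate_target, draw_variable_targets
from .network import RunRecord, Simulation
from .params import HomeostasisParams, SimConfig, stdp_config

#: the three homeostatic conditions contrasted throughout
CONDITIONS = ("diffusive", "nondiffusive", "variable_target")


@dataclass
class Scale:
    """Problem sizes, phase durations, and time compression for one run.

    ``accel`` compresses the homeostatic timescales for desk-scale runs:
    tau_HIP is divided by it while the NO decay rate and the diffusion
    coefficient are multiplied by it, which shortens every homeostatic
    transient by the same factor but leaves the diffusive range
    sqrt(D/lambda) -- the spatial structure of the signal -- unchanged.
    ``accel = 1`` is the reference (full-scale) parameter set.
    """

    n: int = 1000
    ds_um: float = 10.0
    grid_mm: float | None = None   # None keeps the reference 1 mm patch
    t_calib_s: float = 100.0
    t_homeo_s: float = 150.0
    t_meas_s: float = 40.0
    accel: float = 1.0


def make_config(scale: Scale, base: SimConfig | None = None,
                chem_kw: dict | None = None, **homeo_kw) -> SimConfig:
    cfg = base if base is not None else SimConfig()
    cfg = cfg.scaled(scale.n, ds=scale.ds_um, grid_mm=scale.grid_mm)
    if scale.accel != 1.0:
        a = float(scale.accel)
        cfg = replace(
            cfg,
            chem=replace(cfg.chem, lambda_decay=cfg.chem.lambda_decay * a,
                         D=cfg.chem.D * a),
            homeo=replace(cfg.homeo, tau_hip=cfg.homeo.tau_hip / a,
                          tau_diffusive=cfg.homeo.tau_diffusive / a,
                          tau_nondiffusive=cfg.homeo.tau_nondiffusive / a),
        )
    if chem_kw:
        cfg = replace(cfg, chem=replace(cfg.chem, **chem_kw))
    if homeo_kw:
        cfg = replace(cfg, homeo=replace(cfg.homeo, **homeo_kw))
    return cfg


#: desk-scale preset: 640 neurons on a 0.36 mm patch (the reference density
#: of ~5000 neurons/mm^2), 5 um grid, homeostasis accelerated 5x (see
#: docs/methods.md for the rationale)
REDUCED = Scale(n=640, ds_um=5.0, grid_mm=0.36, t_calib_s=30.0,
                t_homeo_s=100.0, t_meas_s=25.0, accel=5.0)


def steady_state_network(
    mode: str,
    seed: int,
    scale: Scale,
    drive: inputs.ExternalDrive | None = None,
    drive_mean: float = 10.0,
    drive_sd: float = 10.0,
    calib_rate_hz: float = 5.0,
    base_config: SimConfig | None = None,
    homeo_kw: dict | None = None,
    chem_kw: dict | None = None,
    stdp: bool = False,
    pattern_segments: np.ndarray | None = None,
    seg_len_s: float = 1.0,
) -> tuple[Simulation, inputs.ExternalDrive, RunRecord]:
    """Calibrate targets and run homeostasis to (near) steady state.

    Returns the simulation (ready for frozen-homeostasis probes), the
    drive used during homeostasis, and the homeostasis-phase record.
    """
    cfg = make_config(scale, base=base_config, chem_kw=chem_kw,
                      mode=mode, **(homeo_kw or {}))
    sim = Simulation(cfg, seed=seed)
    if stdp:
        sim.set_stdp_initial_weights()
    if drive is None:
        drive = inputs.draw_static_rates(scale.n, drive_mean, drive_sd, seed=sim.rng)

    calibrate_target(sim, rate_hz=calib_rate_hz, duration_s=scale.t_calib_s)
    if mode == "variable_target":
        draw_variable_targets(sim, seed=sim.rng, duration_s=scale.t_calib_s)

    if pattern_segments is not None:
        rec = sim.run(scale.t_homeo_s, pattern_segments, mode=mode,
                      seg_len_s=seg_len_s, stdp=stdp)
    else:
        rec = sim.run(scale.t_homeo_s, drive.rates, mode=mode, stdp=stdp)
    return sim, drive, rec


def measure_rates(sim: Simulation, rates_hz, t_meas_s: float) -> metrics.RateSummary:
    """Per-neuron mean rates over a frozen-homeostasis window."""
    rec = sim.run(t_meas_s, rates_hz, mode="off")
    return metrics.RateSummary(rates=rec.mean_rates(), window_s=t_meas_s)


def probe_linearity(
    sim: Simulation, drive: inputs.ExternalDrive, scale: Scale, seed=None,
) -> dict:
    """Freeze homeostasis, redraw inputs from the same distribution, fit dnu vs dmu.

    Input changes are differences of the delivered (clipped) Poisson rates.
    Returns the R^2 together with the population rates before and after.
    """
    before = measure_rates(sim, drive.rates, scale.t_meas_s)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = float(np.mean(drive.raw_rates))
    sd = float(np.std(drive.raw_rates))
    new_drive = inputs.draw_static_rates(drive.n, mean, sd, seed=rng)
    after = measure_rates(sim, new_drive.rates, scale.t_meas_s)
    dmu = new_drive.rates - drive.rates
    dnu = after.rates - before.rates
    return dict(
        r2=metrics.response_r2(dmu, dnu),
        dmu=dmu, dnu=dnu,
        pop_rate_before=before.mean, pop_rate_after=after.mean,
        rates_before=before, rates_after=after,
    )


def experiment_steady_and_linearity(
    seed: int, scale: Scale, modes=CONDITIONS, base_config: SimConfig | None = None,
) -> dict:
    """Steady-state rate distributions and response linearity per condition.

    The central contrast: diffusive homeostasis keeps a broad, heavy-tailed
    rate distribution and a linear population response; non-diffusive
    homeostasis narrows the distribution and rectifies the response;
    variable targets restore breadth but not linearity.
    """
    out = {}
    for k, mode in enumerate(modes):
        sim, drive, rec = steady_state_network(
            mode, seed + 1000 * k, scale, base_config=base_config)
        summary = metrics.RateSummary(
            rates=rec.rates[-max(1, int(scale.t_meas_s / rec.bin_s)):].mean(axis=0),
            window_s=scale.t_meas_s,
        )
        probe = probe_linearity(sim, drive, scale, seed=sim.rng)
        out[mode] = dict(
            sim=sim, drive=drive, homeo_record=rec,
            rate_summary=summary, thresholds=sim.theta.copy(), **probe,
        )
    return out


def experiment_input_groups(
    mode: str, seed: int, scale: Scale,
    group_size: int | None = None, background_hz: float = 2.5,
    elevated_hz: tuple = (10.0, 5.0), t_max_s: float = 400.0,
    smooth_s: float = 20.0,
) -> dict:
    """Persistence of elevated-input group differences under homeostasis.

    Two random excitatory groups receive elevated Poisson input while the
    rest stays at the background rate; homeostasis (calibrated at the
    background rate) runs throughout.  The persistence time is when the
    SNR between the two elevated groups' smoothed rate distributions
    first falls below zero (``inf`` = censored at ``t_max_s``).
    """
    if group_size is None:
        group_size = max(24, round(0.05 * scale.n))  # reference: 250 of N = 5000
    cfg = make_config(scale, mode=mode)
    sim = Simulation(cfg, seed=seed)
    calibrate_target(sim, rate_hz=background_hz, duration_s=scale.t_calib_s)
    if mode == "variable_target":
        draw_variable_targets(sim, seed=sim.rng, duration_s=scale.t_calib_s)

    labels = inputs.assign_groups(
        scale.n, [group_size, group_size], seed=sim.rng,
        eligible=np.nonzero(sim.is_exc)[0],
    )
    rates = np.full(scale.n, background_hz)
    rates[labels == 1] = elevated_hz[0]
    rates[labels == 2] = elevated_hz[1]

    rec = sim.run(t_max_s, rates, mode=mode)
    g1 = rec.rates[:, labels == 1]
    g2 = rec.rates[:, labels == 2]
    t_persist = metrics.persistence_time(g1, g2, bin_s=rec.bin_s, smooth_s=smooth_s)
    return dict(
        persistence_s=t_persist, record=rec, labels=labels,
        thresholds=sim.theta.copy(), drive=rates, sim=sim,
    )


def experiment_combined_timescales(
    ratios, seed: int, scale: Scale, tau_diffusive_ms: float = 2500.0,
) -> list[dict]:
    """Networks with both mechanisms: variance and R^2 versus the timescale ratio.

    ``ratios`` are tau_nondiffusive / tau_diffusive; slower non-diffusive
    homeostasis (larger ratio) shifts the network toward diffusive-only
    behavior (broader rates, more linear response).
    """
    rows = []
    for k, ratio in enumerate(ratios):
        sim, drive, rec = steady_state_network(
            "combined", seed + 137 * k, scale,
            homeo_kw=dict(
                tau_diffusive=tau_diffusive_ms / scale.accel,
                tau_nondiffusive=float(ratio) * tau_diffusive_ms / scale.accel,
            ),
        )
        summary = metrics.RateSummary(
            rates=rec.rates[-max(1, int(scale.t_meas_s / rec.bin_s)):].mean(axis=0),
            window_s=scale.t_meas_s,
        )
        probe = probe_linearity(sim, drive, scale, seed=sim.rng)
        rows.append(dict(ratio=float(ratio), rate_variance=summary.variance,
                         r2=probe["r2"], summary=summary))
    return rows


def experiment_diffusion_sweep(
    D_values, seed: int, scale: Scale, mode: str = "diffusive",
) -> list[dict]:
    """Steady-state rate variance as the diffusion coefficient is varied.

    ``D_values`` are in reference (unaccelerated) um^2/s; the preset's
    time compression is applied on top.  Slower diffusion makes the NO
    signal more local, narrowing the rate distribution toward the
    non-diffusive limit.
    """
    rows = []
    for k, D in enumerate(D_values):
        sim, drive, rec = steady_state_network(
            mode, seed + 211 * k, scale,
            chem_kw=dict(D=float(D) * scale.accel),
        )
        summary = metrics.RateSummary(
            rates=rec.rates[-max(1, int(scale.t_meas_s / rec.bin_s)):].mean(axis=0),
            window_s=scale.t_meas_s,
        )
        rows.append(dict(D=float(D), rate_variance=summary.variance, summary=summary))
    return rows


def experiment_tracking(
    mode: str, seed: int, scale: Scale,
    group_size: int | None = None, pattern_sd: float = 25.0,
    t_eval_s: float = 200.0, eval_group: int = 1,
) -> dict:
    """Tracking of a time-varying group input pattern after homeostasis.

    Excitatory neurons are partitioned into groups; each group's external
    rate is offset by an independent N(0, sd^2) Hz draw per 1 s step, both
    during homeostasis and during the frozen evaluation phase.  The
    response is the evaluated group's mean-rate deviation from the
    population mean; the error is the RMS between z-scored pattern and
    response.
    """
    if group_size is None:
        group_size = max(24, round(0.05 * scale.n))  # reference: 250 of N = 5000
    cfg = make_config(scale, mode=mode)
    sim = Simulation(cfg, seed=seed)
    calibrate_target(sim, rate_hz=5.0, duration_s=scale.t_calib_s)
    if mode == "variable_target":
        draw_variable_targets(sim, seed=sim.rng, duration_s=scale.t_calib_s)

    exc_idx = np.nonzero(sim.is_exc)[0]
    n_groups = len(exc_idx) // group_size
    labels = inputs.assign_groups(
        scale.n, [group_size] * n_groups, seed=sim.rng, eligible=exc_idx)
    drive = inputs.draw_static_rates(scale.n, 10.0, 10.0, seed=sim.rng)

    pat_homeo = inputs.time_varying_pattern(
        n_groups, scale.t_homeo_s, sd=pattern_sd, seed=sim.rng)
    sim.run(scale.t_homeo_s, inputs.pattern_drive(drive.rates, labels, pat_homeo),
            mode=mode, seg_len_s=pat_homeo.dt_pattern)

    pat_eval = inputs.time_varying_pattern(n_groups, t_eval_s, sd=pattern_sd, seed=sim.rng)
    rec = sim.run(t_eval_s, inputs.pattern_drive(drive.rates, labels, pat_eval),
                  mode="off", seg_len_s=pat_eval.dt_pattern)

    group_rate = rec.rates[:, labels == eval_group].mean(axis=1)
    response = group_rate - rec.population_rate()
    pattern = pat_eval.group_rates[:, eval_group - 1]
    m = min(len(pattern), len(response))
    rms = metrics.tracking_rms(pattern[:m], response[:m])
    return dict(rms=rms, pattern=pattern[:m], response=response[:m], record=rec, sim=sim)


def experiment_orientation(
    sim: Simulation, seed: int, n_trials: int = 24, t_trial_s: float = 1.0,
    base_rate: float = 20.0, amplitude: float = 2.5, width: float = 90.0,
    t_baseline_s: float = 10.0,
) -> dict:
    """Population-vector decoding of stimulus orientation (frozen homeostasis).

    Each excitatory neuron holds a random preferred orientation; per trial
    a random stimulus angle sets Gaussian-tuned input rates (inhibitory
    neurons receive the untuned base rate), and the stimulus is decoded as
    the angle of the excitatory population vector of stimulus responses
    (trial rates minus each neuron's untuned-baseline rate; at desk scale
    the untuned component would otherwise dominate the vector sum).
    Returns the standard deviation of the signed circular decoding errors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exc = sim.is_exc
    preferred = inputs.assign_preferred_orientations(int(exc.sum()), seed=rng)
    baseline_rec = sim.run(t_baseline_s, np.full(sim.n, base_rate), mode="off")
    baseline = baseline_rec.mean_rates()[exc]
    errors = []
    n_zero = 0
    for _ in range(n_trials):
        theta_s = float(rng.uniform(0.0, 360.0))
        stim = inputs.OrientationStimulus(
            preferred=preferred, stimulus_angle=theta_s,
            base_rate=base_rate, amplitude=amplitude, width=width)
        rates = np.full(sim.n, base_rate)
        rates[exc] = inputs.orientation_rates(stim).rates
        rec = sim.run(t_trial_s, rates, mode="off")
        resp = rec.mean_rates()[exc] - baseline
        try:
            decoded = metrics.population_vector_decode(
                np.clip(resp, 0.0, None), preferred)
        except ValueError:
            n_zero += 1
            continue
        errors.append(metrics.circular_error_deg(decoded, theta_s))
    errors = np.asarray(errors, dtype=float)
    return dict(error_std_deg=float(errors.std()), errors_deg=errors,
                n_zero_vector=n_zero)


def experiment_stdp(
    mode: str, seed: int, scale: Scale,
    t_plastic_s: float = 500.0, record_spikes_s: float = 10.0,
) -> dict:
    """Recurrent E->E STDP combined with homeostasis (J_ext = 40 nS, C = 250).

    Runs plasticity and homeostasis together until the weight distribution
    approaches its bimodal steady state, freezes both, then measures the
    weight histogram, rate distribution, spike statistics, and response
    linearity.  ``mode`` may be any homeostatic condition or ``"off"``
    (no homeostasis).
    """
    base = stdp_config(scale.n).scaled(scale.n, ds=scale.ds_um)
    cfg = make_config(scale, base=base, mode=mode if mode != "off" else "off")
    sim = Simulation(cfg, seed=seed)
    sim.set_stdp_initial_weights()
    drive = inputs.draw_static_rates(scale.n, 10.0, 10.0, seed=sim.rng)
    calibrate_target(sim, rate_hz=5.0, duration_s=scale.t_calib_s)
    if mode == "variable_target":
        draw_variable_targets(sim, seed=sim.rng, duration_s=scale.t_calib_s)

    sim.run(t_plastic_s, drive.rates, mode=mode, stdp=True)

    ee = sim.conn.ee_edge_mask()
    weights = sim.conn.weights[ee].copy()
    rec = sim.run(record_spikes_s, drive.rates, mode="off", record_spikes=True)
    summary = metrics.RateSummary(rates=rec.mean_rates(), window_s=record_spikes_s)
    spk = metrics.spike_statistics(
        rec.spike_t, rec.spike_i, sim.n, record_spikes_s)
    probe = probe_linearity(sim, drive, scale, seed=sim.rng)
    return dict(
        weights=weights,
        bound_fraction=stdp_mod.bound_fraction(weights, cfg.stdp),
        rate_summary=summary, spike_stats=spk, r2=probe["r2"], sim=sim,
        drive=drive,
    )


def experiment_stdp_shuffled(
    mode: str, seed: int, scale: Scale, donor: Simulation,
) -> dict:
    """Shuffled-weight control: static permuted STDP weights, no plasticity.

    Takes the converged E->E weight matrix of a donor STDP network
    (canonically one run without homeostasis), permutes the weight values
    across the existing connections, installs them in a fresh network,
    runs the requested homeostatic condition to steady state without
    STDP, and probes response linearity.
    """
    from dataclasses import replace as _replace

    shuffled = stdp_mod.shuffle_weights(donor.conn, seed=seed)
    conn = _replace(donor.conn, weights=shuffled,
                    positions=donor.conn.positions.copy())
    cfg = _replace(donor.cfg, homeo=_replace(donor.cfg.homeo, mode=mode))
    sim = Simulation(cfg, seed=seed, connectivity=conn)
    calibrate_target(sim, rate_hz=5.0, duration_s=scale.t_calib_s)
    if mode == "variable_target":
        draw_variable_targets(sim, seed=sim.rng, duration_s=scale.t_calib_s)
    drive = inputs.draw_static_rates(scale.n, 10.0, 10.0, seed=sim.rng)
    sim.run(scale.t_homeo_s, drive.rates, mode=mode)
    probe = probe_linearity(sim, drive, scale, seed=sim.rng)
    return dict(r2=probe["r2"], sim=sim, drive=drive)
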