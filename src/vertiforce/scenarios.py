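"""Seeded end-to-end recovery scenarios.

Each scenario generates synthetic data under the instrument's stated
operating conditions, runs the corresponding analysis chain, and returns a
JSON-able report.  These functions back both ``vertiforce reproduce`` and
the repository's acceptance script; identical seeds yield identical
reports.

Pinned conditions (the instrument's operating point):

* cantilever: k = 5.19e-6 N/m (from the published force/shift pair
  2.7 fN / 0.52 nm), tau = 0.125 ms, T = 295 K, sampled at 48 kHz;
* force modulation: 1 Hz square wave, duty 0.5, 16-minute accumulation;
* tilt sweeps: ±2 degrees in 0.17-degree motor steps, evanescent decay
  length 150 nm;
* stepping: 2.79 nm mean / 0.52 nm SD downward steps (the published
  smallest-step statistics), 0.3 nm readout noise;
* drift: 2.0 nm/min in-plane ramp under 1-nm correlated noise;
* cross-talk: 2 % fast-to-slow coupling, 0.05 % rms position noise.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version

import numpy as np

from . import calibration, force_pipeline, stage_metrics, tilt_align
from .actuator_sim import ActuatorConfig, SawtoothWaveform, simulate_stick_slip
from .cantilever_sim import (
    CantileverModel,
    DetectionModel,
    DriftModel,
    ModulationSchedule,
    generate_staircase,
    simulate_raster_scan,
    simulate_sum_signal,
    simulate_tip_trace,
)
from .constants import BOLTZMANN

SCENARIOS = ("fig6", "tilt", "steps", "drift", "crosstalk", "stickslip")

# operating point shared by the force scenarios
STIFFNESS = 5.19e-6          # N/m
CORR_TIME = 0.125e-3         # s
TEMPERATURE = 295.0          # K
SAMPLING_RATE = 48_000.0     # Hz
MOD_FREQ = 1.0               # Hz
FORCE_ON = 2.7e-15           # N


def _package_version() -> str:
    try:
        return version("vertiforce")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _report(scenario: str, seed: int, params: dict, results: dict) -> dict:
    body = {"scenario": scenario, "seed": int(seed),
            "package_version": _package_version(),
            "parameters": params, "results": results}
    digest = hashlib.sha1(json.dumps(params, sort_keys=True).encode()).hexdigest()
    body["config_hash"] = digest[:12]
    return body


def run_fig6(seed: int = 1, duration: float = 960.0,
             force_on: float = FORCE_ON) -> dict:
    """Intermittent-mode force recovery on a 16-minute synthetic recording.

    Simulates the modulated OU tip trace, calibrates the stiffness from
    per-minute off-state power spectra, and runs the full decimate/split/
    shift/force pipeline.  Expected outputs near 0.52 nm and 2.7 fN.
    """
    model = CantileverModel(stiffness=STIFFNESS, correlation_time=CORR_TIME,
                            temperature=TEMPERATURE)
    schedule = ModulationSchedule(frequency=MOD_FREQ, duty=0.5, force_on=force_on)
    trace = simulate_tip_trace(model, DetectionModel(), schedule,
                               duration=duration, fs=SAMPLING_RATE, seed=seed)

    # stiffness calibration: Lorentzian fits of the off-state PSD, one fit
    # per minute of data, aggregated into a stiffness distribution
    settle = 5.0 * CORR_TIME
    split = force_pipeline.split_by_modulation(trace, schedule, settle)
    off_mask = split.state == 0
    off_full = trace.samples[off_mask]
    fits = []
    chunk = int(60.0 * SAMPLING_RATE * (1.0 - schedule.duty))  # ~1 min of off data
    seg = 4096
    n_chunks = max(1, off_full.size // chunk)
    for i in range(n_chunks):
        block = off_full[i * chunk:(i + 1) * chunk]
        if block.size < seg:
            continue
        psd = calibration.estimate_psd(
            _as_trace(block, SAMPLING_RATE), segment_length=seg)
        fits.append(calibration.fit_lorentzian(psd, TEMPERATURE,
                                               sampling_rate=SAMPLING_RATE))
    k_dist = calibration.StiffnessDistribution.from_values(
        [f.stiffness for f in fits],
        single_fit_se=fits[-1].stiffness_se if fits else None)

    acc = force_pipeline.accumulate(trace, schedule, k_dist, CORR_TIME,
                                    settle_discard=settle)
    res = acc.force.as_dict()
    res.update({
        "k_fit_mean_N_m": k_dist.mean,
        "k_fit_sd_N_m": k_dist.sd,
        "k_true_N_m": STIFFNESS,
        "fc_fit_hz": fits[-1].fc if fits else None,
        "n_k_fits": k_dist.n,
        "expected_shift_nm": force_on / STIFFNESS * 1e9,
        "shift_tolerance_nm": 3.0 * acc.force.shift_se * 1e9,
        "shift_pass": bool(abs(acc.force.shift - force_on / STIFFNESS)
                           <= 3.0 * acc.force.shift_se),
        "expected_force_fN": force_on * 1e15,
        "force_tolerance_fN": 3.0 * acc.force.force_se * 1e15,
        "force_pass": bool(abs(acc.force.force - force_on)
                           <= 3.0 * acc.force.force_se),
    })
    params = {"k_N_m": STIFFNESS, "tau_s": CORR_TIME, "T_K": TEMPERATURE,
              "fs_hz": SAMPLING_RATE, "duration_s": duration,
              "force_on_N": force_on, "mod_freq_hz": MOD_FREQ, "duty": 0.5,
              "settle_discard_s": settle}
    return _report("fig6", seed, params, res)


def _as_trace(samples: np.ndarray, fs: float):
    from .trace import PositionTrace

    return PositionTrace(fs=fs, samples=samples)


def run_tilt(seed: int = 1, n_sweeps: int = 100,
             amp_noise_frac: float = 0.05, phase_noise_deg: float = 10.0,
             grid_step: float = 0.17, grid_half_span: float = 2.0) -> dict:
    """Tilt-zero routine: deterministic phase flip plus noisy-sweep Monte Carlo."""
    # deterministic flip check on raw synthetic sum signals
    det = DetectionModel()
    kw = dict(drive_freq=1000.0, drive_amp=5e-9, detection=det,
              duration=0.05, fs=SAMPLING_RATE, noise_frac=0.0, seed=0)
    _, phi_neg = tilt_align.lockin(simulate_sum_signal(-5.0, **kw), 1000.0)
    _, phi_pos = tilt_align.lockin(simulate_sum_signal(+5.0, **kw), 1000.0)
    flip = abs(float(tilt_align._wrap_deg(phi_pos - phi_neg)))

    # noisy Monte Carlo on the demodulated response
    angles = np.arange(-grid_half_span, grid_half_span + 1e-9, grid_step)
    rng = np.random.default_rng(seed)
    errors = []
    n_found = 0
    for _ in range(n_sweeps):
        resp = tilt_align.synthesize_tilt_response(
            angles, amp_noise_frac=amp_noise_frac,
            phase_noise_deg=phase_noise_deg,
            seed=int(rng.integers(0, 2**31 - 1)))
        est = tilt_align.find_vertical(resp)
        if est.flip_found and est.theta0 is not None:
            n_found += 1
            errors.append(abs(est.theta0))
    errors = np.sort(np.array(errors))
    # smallest bound holding in >=95% of the sweeps
    q95 = float(errors[min(int(np.ceil(0.95 * n_sweeps)) - 1, errors.size - 1)])
    results = {
        "phase_flip_deg": flip,
        "n_sweeps": n_sweeps,
        "n_flip_found": n_found,
        "abs_error_q95_deg": q95,
        "abs_error_max_deg": float(errors.max()),
        "within_resolution_count": int(np.sum(errors <= grid_step)),
        "grid_step_deg": grid_step,
    }
    params = {"grid_step_deg": grid_step, "grid_half_span_deg": grid_half_span,
              "amp_noise_frac": amp_noise_frac,
              "phase_noise_deg": phase_noise_deg, "n_sweeps": n_sweeps}
    return _report("tilt", seed, params, results)


def run_steps(seed: int = 1, n_steps: int = 200, mean_step: float = 2.79e-9,
              sd_step: float = 0.52e-9, noise_sd: float = 0.3e-9,
              dwell: float = 0.2, fs: float = 1000.0) -> dict:
    """Step-statistics recovery on a downward staircase."""
    trace, true_steps = generate_staircase(
        n_steps, mean_step=mean_step, sd_step=sd_step, dwell=dwell, fs=fs,
        noise_sd=noise_sd, direction="down", seed=seed)
    stats = stage_metrics.detect_steps(trace, window=50, threshold_sigma=5.0,
                                       min_dwell=100)
    gen_sem = np.std(true_steps, ddof=1) / np.sqrt(true_steps.size)
    combined_sem = float(np.hypot(gen_sem, stats.sem))
    results = {
        "mean_step_nm": abs(stats.mean) * 1e9,
        "mean_step_signed_nm": stats.mean * 1e9,
        "sem_nm": stats.sem * 1e9,
        "sd_nm": stats.sd * 1e9,
        "n_detected": stats.n,
        "n_true": int(true_steps.size),
        "true_mean_nm": abs(float(true_steps.mean())) * 1e9,
        "combined_sem_nm": combined_sem * 1e9,
        "direction": stats.direction,
    }
    params = {"n_steps": n_steps, "mean_step_nm": mean_step * 1e9,
              "sd_step_nm": sd_step * 1e9, "noise_sd_nm": noise_sd * 1e9,
              "dwell_s": dwell, "fs_hz": fs}
    return _report("steps", seed, params, results)


def run_drift(seed: int = 1, rate_nm_min: float = 2.0, duration: float = 1800.0,
              fs: float = 10.0, noise_sd: float = 1e-9,
              noise_tau: float = 1.0) -> dict:
    """Drift-velocity recovery: linear ramp under correlated (OU) noise."""
    velocity = rate_nm_min * 1e-9 / 60.0
    # stationary OU noise of the requested SD realized via equipartition
    k_noise = BOLTZMANN * TEMPERATURE / noise_sd**2
    model = CantileverModel(stiffness=k_noise, correlation_time=noise_tau,
                            temperature=TEMPERATURE)
    trace = simulate_tip_trace(model, drift=DriftModel(velocity=velocity),
                               duration=duration, fs=fs, seed=seed)
    est = stage_metrics.estimate_drift(trace)
    results = {
        "velocity_nm_min": est.nm_per_min,
        "se_nm_min": est.se_nm_per_min,
        "true_velocity_nm_min": rate_nm_min,
        "error_nm_min": est.nm_per_min - rate_nm_min,
    }
    params = {"rate_nm_min": rate_nm_min, "duration_s": duration, "fs_hz": fs,
              "noise_sd_nm": noise_sd * 1e9, "noise_tau_s": noise_tau}
    return _report("drift", seed, params, results)


def run_crosstalk(seed: int = 1, coupling: float = 0.02, n_lines: int = 20,
                  line_length: float = 1e-6, noise_frac: float = 5e-4) -> dict:
    """Cross-talk estimation and linear correction on a serpentine raster.

    The coupling is fitted on a calibration scan and the correction is then
    applied to an independently noisy validation scan, where the residual
    coupling is re-measured — re-fitting the calibration scan itself would
    return zero by construction and say nothing about the correction.
    """
    noise_sd = noise_frac * line_length
    cal = simulate_raster_scan(0.0, coupling, n_lines=n_lines,
                               line_length=line_length, noise_sd=noise_sd,
                               seed=seed)
    res = stage_metrics.estimate_crosstalk(cal)
    val = simulate_raster_scan(0.0, coupling, n_lines=n_lines,
                               line_length=line_length, noise_sd=noise_sd,
                               seed=seed + 1)
    corrected = stage_metrics.apply_crosstalk_correction(val, res.c_yx)
    residual = stage_metrics.estimate_crosstalk(corrected)
    results = {
        "c_yx_estimated": res.c_yx,
        "c_yx_true": coupling,
        "residual_pct": 100.0 * abs(residual.c_yx),
        "fit_se": res.fit_se,
    }
    params = {"coupling": coupling, "n_lines": n_lines,
              "line_length_m": line_length, "noise_frac": noise_frac}
    return _report("crosstalk", seed, params, results)


def run_stickslip(seed: int = 1, shuttle_mass: float = 0.7e-3,
                  static_friction: float = 0.02, kinetic_friction: float = 0.015,
                  amplitude: float = 100e-9, ramp_time: float = 1e-3,
                  decay_constant: float = 20e-6, n_cycles: int = 5) -> dict:
    """Stick-slip stepping: gate check plus per-cycle displacement."""
    cfg = ActuatorConfig(shuttle_mass=shuttle_mass,
                         static_friction=static_friction,
                         kinetic_friction=kinetic_friction,
                         orientation="vertical")
    wave = SawtoothWaveform(amplitude=amplitude, ramp_time=ramp_time,
                            decay_constant=decay_constant,
                            period=ramp_time + 10 * decay_constant,
                            n_cycles=n_cycles)
    trace = simulate_stick_slip(cfg, wave)
    from .actuator_sim import slip_threshold

    # sub-threshold drive: same shape, amplitude too small to break stick
    gentle = SawtoothWaveform(amplitude=1e-12, ramp_time=ramp_time,
                              decay_constant=decay_constant,
                              period=ramp_time + 10 * decay_constant,
                              n_cycles=n_cycles)
    gentle_trace = simulate_stick_slip(cfg, gentle)
    results = {
        "slip_threshold_m_s2": slip_threshold(cfg),
        "mean_cycle_displacement_nm": float(np.mean(trace.cycle_displacements)) * 1e9,
        "net_displacement_nm": trace.net_displacement * 1e9,
        "subthreshold_net_displacement_nm": gentle_trace.net_displacement * 1e9,
        "n_cycles": n_cycles,
    }
    params = {"shuttle_mass_kg": shuttle_mass, "static_friction_N": static_friction,
              "kinetic_friction_N": kinetic_friction, "amplitude_nm": amplitude * 1e9,
              "ramp_time_s": ramp_time, "decay_constant_s": decay_constant,
              "n_cycles": n_cycles}
    return _report("stickslip", seed, params, results)


_RUNNERS = {
    "fig6": run_fig6,
    "tilt": run_tilt,
    "steps": run_steps,
    "drift": run_drift,
    "crosstalk": run_crosstalk,
    "stickslip": run_stickslip,
}


def reproduce(scenario: str, seed: int = 1, **overrides) -> dict:
    """Run a named recovery scenario with pinned defaults."""
    if scenario not in _RUNNERS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid names: {', '.join(SCENARIOS)}"
        )
    return _RUNNERS[scenario](seed=seed, **overrides)
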