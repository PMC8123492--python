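"""Synthetic-data generators for a vertically oriented, ultra-compliant cantilever.

The tip of a vertical cantilever bound by a harmonic restoring force and
immersed in a thermal bath follows overdamped Langevin dynamics, i.e. an
Ornstein–Uhlenbeck (OU) process

    dx = -(x - F(t)/k) / tau * dt + sqrt(2 kB T / (k tau)) dW,

with stationary variance ``kB*T/k`` (equipartition) and autocorrelation
``exp(-|dt|/tau)``.  The generator uses the *exact* discretization of this
process — decay factor ``exp(-dt/tau)`` and innovation variance
``(kB*T/k) * (1 - exp(-2 dt/tau))`` — so the sample statistics are correct at
any step size, not merely in the small-step limit.

Also provided: the evanescent-field sum-signal model used by the tilt
alignment routine, a serpentine raster scan with linear axis cross-talk, a
staircase generator emulating stick-slip stepping records, and the
minimum-stiffness tilt rule for vertical probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .constants import BOLTZMANN
from .trace import MOD_OFF, MOD_ON, PositionTrace


@dataclass(frozen=True)
class CantileverModel:
    """Physical parameters of the harmonically bound thermal probe.

    Parameters
    ----------
    stiffness : float
        Spring constant k, N/m.  Ultra-compliant vertical probes sit in the
        1e-6 – 1e-5 N/m range.
    correlation_time : float
        OU correlation time tau, s (the reciprocal of 2*pi times the
        Lorentzian corner frequency).
    temperature : float
        Bath temperature, K.
    initial_position : float
        Position of the first sample, m.
    """

    stiffness: float
    correlation_time: float
    temperature: float = 295.0
    initial_position: float = 0.0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")
        if self.correlation_time <= 0:
            raise ValueError("correlation_time must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def drag(self) -> float:
        """Drag coefficient gamma = k * tau, kg/s."""
        return self.stiffness * self.correlation_time

    @property
    def corner_frequency(self) -> float:
        """Lorentzian corner frequency fc = 1 / (2 pi tau), Hz."""
        return 1.0 / (2.0 * np.pi * self.correlation_time)

    @property
    def thermal_variance(self) -> float:
        """Equipartition position variance kB*T/k, m^2."""
        return BOLTZMANN * self.temperature / self.stiffness


@dataclass(frozen=True)
class ModulationSchedule:
    """Square-wave on/off force modulation (TTL-style).

    The state at time t is *on* when ``frac((t - phase_offset) * frequency)``
    is below ``duty`` and *off* otherwise.
    """

    frequency: float
    duty: float = 0.5
    force_on: float = 0.0
    force_off: float = 0.0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("modulation frequency must be positive")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie strictly between 0 and 1")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Fractional cycle phase in [0, 1) at times ``t`` (seconds)."""
        return ((np.asarray(t, dtype=float) - self.phase_offset) * self.frequency) % 1.0

    def state(self, t: np.ndarray) -> np.ndarray:
        """int8 on/off codes at times ``t``."""
        return np.where(self.phase(t) < self.duty, MOD_ON, MOD_OFF).astype(np.int8)

    def force(self, t: np.ndarray) -> np.ndarray:
        """Applied force (N) at times ``t``."""
        return np.where(self.phase(t) < self.duty, self.force_on, self.force_off)


@dataclass(frozen=True)
class DetectionModel:
    """Scattered-evanescent-wave readout model.

    ``noise_sd`` is additive white Gaussian readout noise on position (m);
    ``decay_length`` is the exponential decay scale of the evanescent field
    (default 150 nm); ``baseline_height`` the resting tip height above the
    interface; ``signal_scale`` an arbitrary intensity unit.
    """

    noise_sd: float = 0.0
    decay_length: float = 150e-9
    baseline_height: float = 50e-9
    signal_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclass(frozen=True)
class DriftModel:
    """Linear mechanical drift: constant velocity (m/s) plus white noise (m)."""

    velocity: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.velocity) and np.isfinite(self.noise_sd)):
            raise ValueError("drift parameters must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_tip_trace(
    model: CantileverModel,
    detection: DetectionModel | None = None,
    modulation: ModulationSchedule | None = None,
    drift: DriftModel | None = None,
    *,
    duration: float,
    fs: float,
    seed: int,
    axis_label: str = "x",
) -> PositionTrace:
    """Simulate a tip-position trace of the thermally fluctuating probe.

    The returned trace is an exact-discretization OU realization with
    stationary variance ``kB*T/k``, autocorrelation ``exp(-|dt|/tau)`` and
    mean ``F(t)/k`` under the (quasi-static) modulated force, plus an
    optional drift ramp and additive readout noise.  Identical seeds yield
    identical traces (``numpy.random.default_rng`` streams).

    Parameters
    ----------
    duration, fs : float
        Trace length (s) and sampling rate (Hz); ``duration*fs >= 2``.
    seed : int
        Seed for the single RNG used by this call.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration*fs must be at least 2 samples")
    if fs * model.correlation_time < 2:
        warnings.warn(
            "fs*tau < 2: the correlation time is under-resolved; "
            "spectra will be aliased",
            stacklevel=2,
        )

    dt = 1.0 / fs
    decay = np.exp(-dt / model.correlation_time)
    var = model.thermal_variance
    innov_sd = np.sqrt(var * (1.0 - decay * decay))
    rng = np.random.default_rng(seed)

    t = np.arange(n) * dt
    if modulation is not None:
        mean_path = modulation.force(t) / model.stiffness
        mod_state = modulation.state(t)
    else:
        mean_path = np.zeros(n)
        mod_state = None

    # x[i] = decay*x[i-1] + (1-decay)*mu[i-1] + eta[i]; driven form solved
    # with an IIR filter so multi-minute 48 kHz traces stay fast.
    u = (1.0 - decay) * mean_path
    u = np.roll(u, 1)
    if innov_sd > 0:
        u += rng.normal(0.0, innov_sd, n)
    # u[0] chosen so the filtered x[0] equals x0 exactly (no innovation there)
    u[0] = (1.0 - decay) * model.initial_position
    x, _ = lfilter([1.0], [1.0, -decay], u, zi=np.array([decay * model.initial_position]))

    if drift is not None:
        if drift.velocity != 0.0:
            x += drift.velocity * t
        if drift.noise_sd > 0:
            x += rng.normal(0.0, drift.noise_sd, n)
    if detection is not None and detection.noise_sd > 0:
        x += rng.normal(0.0, detection.noise_sd, n)

    return PositionTrace(
        fs=fs,
        samples=x,
        mod_state=mod_state,
        axis_label=axis_label,
        meta={"seed": int(seed), "k_N_m": model.stiffness, "tau_s": model.correlation_time,
              "temperature_K": model.temperature},
    )


def simulate_sum_signal(
    tilt_deg: float,
    *,
    drive_freq: float,
    drive_amp: float,
    detection: DetectionModel | None = None,
    duration: float = 0.1,
    fs: float = 48_000.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> PositionTrace:
    """Sum-signal trace under acoustic drive at a given cantilever tilt.

    A tilted probe oscillating along its axis with amplitude ``drive_amp``
    moves vertically by ``drive_amp*sin(tilt)``; the evanescent readout
    transduces that exponentially:

        s(t) = S0 * exp(-(z0 + drive_amp*sin(tilt)*sin(2 pi f t)) / d) * (1 + eta)

    with multiplicative white noise ``eta`` of SD ``noise_frac``.  The
    demodulated amplitude at the drive frequency is proportional to
    ``|sin(tilt)|`` for small ``drive_amp/d``, and its phase flips by 180
    degrees when ``sin(tilt)`` changes sign — the signature the tilt-zero
    routine looks for.
    """
    if abs(tilt_deg) >= 90:
        raise ValueError("tilt angle must satisfy |tilt| < 90 degrees")
    if fs <= 2 * drive_freq:
        raise ValueError("fs must exceed twice the drive frequency")
    det = detection or DetectionModel()
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short")
    t = np.arange(n) / fs
    dz = drive_amp * np.sin(np.deg2rad(tilt_deg)) * np.sin(2 * np.pi * drive_freq * t)
    s = det.signal_scale * np.exp(-(det.baseline_height + dz) / det.decay_length)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        s = s * (1.0 + rng.normal(0.0, noise_frac, n))
    return PositionTrace(fs=fs, samples=s, axis_label="sum",
                         meta={"tilt_deg": float(tilt_deg), "drive_freq_hz": drive_freq,
                               "seed": int(seed)})


@dataclass
class RasterScan:
    """Paired commanded/measured two-axis serpentine raster scan (metres)."""

    cmd_x: np.ndarray
    cmd_y: np.ndarray
    meas_x: np.ndarray
    meas_y: np.ndarray
    line_index: np.ndarray
    samples_per_line: int

    def __post_init__(self) -> None:
        n = len(self.cmd_x)
        for arr in (self.cmd_y, self.meas_x, self.meas_y, self.line_index):
            if len(arr) != n:
                raise ValueError("all raster arrays must share one length")

    @property
    def n_lines(self) -> int:
        return int(self.line_index.max()) + 1


def simulate_raster_scan(
    crosstalk_xy: float,
    crosstalk_yx: float,
    *,
    n_lines: int,
    line_length: float,
    noise_sd: float = 0.0,
    samples_per_line: int = 256,
    seed: int = 0,
) -> RasterScan:
    """Serpentine raster with a constant linear coupling between the axes.

    The measured position is ``[[1, c_xy], [c_yx, 1]] @ commanded`` plus
    isotropic white noise.  x is the fast axis; y steps once per line.
    """
    if abs(crosstalk_xy) >= 1 or abs(crosstalk_yx) >= 1:
        raise ValueError("|crosstalk| must be < 1")
    if n_lines < 2:
        raise ValueError("a raster needs at least 2 lines (slow axis undefined)")
    ramp = np.linspace(0.0, line_length, samples_per_line)
    pitch = line_length / (n_lines - 1)
    cx, cy, li = [], [], []
    for j in range(n_lines):
        cx.append(ramp if j % 2 == 0 else ramp[::-1])
        cy.append(np.full(samples_per_line, j * pitch))
        li.append(np.full(samples_per_line, j, dtype=int))
    cmd_x = np.concatenate(cx)
    cmd_y = np.concatenate(cy)
    meas_x = cmd_x + crosstalk_xy * cmd_y
    meas_y = cmd_y + crosstalk_yx * cmd_x
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        meas_x = meas_x + rng.normal(0.0, noise_sd, meas_x.size)
        meas_y = meas_y + rng.normal(0.0, noise_sd, meas_y.size)
    return RasterScan(cmd_x, cmd_y, meas_x, meas_y, np.concatenate(li), samples_per_line)


def generate_staircase(
    n_steps: int,
    *,
    mean_step: float,
    sd_step: float,
    dwell: float,
    fs: float,
    noise_sd: float = 0.0,
    direction: str = "up",
    seed: int = 0,
) -> tuple[PositionTrace, np.ndarray]:
    """Piecewise-constant staircase emulating stick-slip stepping records.

    Step increments are drawn from ``Normal(mean_step, sd_step**2)`` and
    signed by ``direction``; white readout noise is added on top.  Returns
    the trace together with the true (signed) step sizes so detector tests
    have an exact oracle.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if sd_step < 0:
        raise ValueError("sd_step must be non-negative")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    dwell_samples = int(round(dwell * fs))
    if dwell_samples < 4:
        raise ValueError("dwell*fs must be at least 4 samples per level")
    rng = np.random.default_rng(seed)
    sign = 1.0 if direction == "up" else -1.0
    steps = sign * rng.normal(mean_step, sd_step, n_steps)
    levels = np.concatenate([[0.0], np.cumsum(steps)])
    x = np.repeat(levels, dwell_samples)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.size)
    trace = PositionTrace(fs=fs, samples=x, axis_label="z",
                          meta={"seed": int(seed), "n_steps": n_steps})
    return trace, steps


def min_stiffness_factor(theta_deg: float) -> float:
    """Tilt scaling of the minimum stiffness that avoids jump-to-contact.

    For a probe tilted by ``theta`` from the vertical the minimum stiffness
    scales as ``cos^2(90 deg - theta) = sin^2(theta)``: a perfectly vertical
    probe (theta=0) has no jump-to-contact constraint at all, which is what
    permits 1e-6 N/m-class cantilevers.
    """
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError("theta must lie in [0, 90] degrees")
    return float(np.sin(np.deg2rad(theta_deg)) ** 2)
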