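"""Lock-in demodulation and automatic tilt-zero (vertical-angle) finding.

An acoustically driven cantilever that is not perfectly vertical oscillates
vertically, modulating the evanescent sum signal at the drive frequency.
The demodulated amplitude is proportional to ``|sin(tilt)|`` and its phase
flips by 180 degrees as the tilt passes through zero, so the vertical
orientation is found by locating the minimum-amplitude angle that carries a
sudden phase reversal.  Amplitude alone is not enough: ``|sin(theta)|`` has
a cusp (not a parabola) at zero, and a noisy minimum without the phase flip
is ambiguous — hence the routine requires both signatures to agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import PositionTrace


def _wrap_deg(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(phi) + 180.0) % 360.0 - 180.0)


def lockin(sig: PositionTrace, f_ref: float) -> tuple[float, float]:
    """Demodulate a signal at a reference frequency.

    Returns ``(R, phi_deg)`` with ``R = 2*|<s(t) exp(-i 2 pi f t)>|`` over
    whole reference periods and the convention ``phi = 0`` for
    ``s ∝ sin(2 pi f t)``.
    """
    if sig.fs <= 2 * f_ref:
        raise ValueError("fs must exceed twice the reference frequency")
    n_per_period = sig.fs / f_ref
    whole = int(np.floor(sig.n / n_per_period))
    if whole < 2:
        raise ValueError("need at least 2 whole reference periods")
    n_use = int(round(whole * n_per_period))
    t = sig.t0 + np.arange(n_use) / sig.fs
    s = sig.samples[:n_use]
    s = s - s.mean()
    z = 2.0 * np.mean(s * np.exp(-2j * np.pi * f_ref * t))
    r = float(np.abs(z))
    phi = float(_wrap_deg(np.degrees(np.angle(z)) + 90.0))
    return r, phi


@dataclass
class TiltResponse:
    """Demodulated amplitude/phase of the sum signal versus tilt angle."""

    angles: np.ndarray           # degrees, strictly increasing
    amplitude: np.ndarray        # arbitrary units
    phase: np.ndarray            # degrees in (-180, 180]
    amplitude_sd: np.ndarray | None = None
    phase_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if not (self.angles.shape == self.amplitude.shape == self.phase.shape):
            raise ValueError("angles, amplitude and phase must share one length")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")


@dataclass
class TiltZeroEstimate:
    """Result of the automatic vertical-angle routine."""

    theta0: float | None
    grid_resolution: float
    phase_jump: float
    flip_found: bool
    amplitude_min_consistent: bool


def sweep_demodulate(signals, angles, f_ref: float) -> TiltResponse:
    """Lock-in each per-angle signal and assemble a tilt response."""
    angles = np.asarray(angles, dtype=float)
    signals = list(signals)
    if angles.size < 3:
        raise ValueError("a sweep needs at least 3 angles")
    if len(signals) != angles.size:
        raise ValueError("one signal per angle required")
    order = np.argsort(angles)
    amp = np.empty(angles.size)
    phase = np.empty(angles.size)
    for i, j in enumerate(order):
        amp[i], phase[i] = lockin(signals[j], f_ref)
    return TiltResponse(angles=angles[order], amplitude=amp, phase=phase)


def synthesize_tilt_response(angles, *, drive_amp: float = 5e-9,
                             decay_length: float = 150e-9,
                             amp_noise_frac: float = 0.0,
                             phase_noise_deg: float = 0.0,
                             seed: int = 0) -> TiltResponse:
    """Analytic tilt response with measurement noise on the demodulated values.

    Amplitude ``∝ |sin(theta)| * drive_amp/d`` with multiplicative Gaussian
    noise; phase 180 degrees for positive tilt and 0 for negative (the
    sum-signal transduction inverts the vertical motion), with additive
    Gaussian phase noise.  Models the per-angle lock-in readings of a real
    sweep without synthesizing raw traces.
    """
    angles = np.sort(np.asarray(angles, dtype=float))
    rng = np.random.default_rng(seed)
    amp = np.abs(np.sin(np.deg2rad(angles))) * drive_amp / decay_length
    phase = np.where(angles >= 0, 180.0, 0.0)
    if amp_noise_frac > 0:
        amp = amp * (1.0 + rng.normal(0.0, amp_noise_frac, angles.size))
        amp = np.abs(amp)
    if phase_noise_deg > 0:
        phase = _wrap_deg(phase + rng.normal(0.0, phase_noise_deg, angles.size))
    return TiltResponse(angles=angles, amplitude=amp, phase=phase)


def find_vertical(resp: TiltResponse, flip_min_deg: float = 90.0) -> TiltZeroEstimate:
    """Locate the tilt-zero: minimum amplitude with an adjacent phase reversal.

    Scans adjacent angle pairs for a circular phase change exceeding
    ``flip_min_deg`` and closest to 180 degrees, requires the grid amplitude
    minimum to lie within one grid point of that pair, and returns the pair
    midpoint.  Multiple reversals mean the sweep is too noisy to trust and
    raise an error; no reversal yields ``flip_found=False``.
    """
    spacing = float(np.mean(np.diff(resp.angles)))
    jumps = np.abs(_wrap_deg(np.diff(resp.phase)))
    candidates = np.nonzero(jumps > flip_min_deg)[0]
    if candidates.size == 0:
        return TiltZeroEstimate(theta0=None, grid_resolution=spacing,
                                phase_jump=float(jumps.max(initial=0.0)),
                                flip_found=False, amplitude_min_consistent=False)
    if candidates.size > 1:
        raise ValueError(
            f"{candidates.size} phase reversals found: sweep too noisy or invalid"
        )
    i = int(candidates[0])
    theta0 = 0.5 * (resp.angles[i] + resp.angles[i + 1])
    amin = int(np.argmin(resp.amplitude))
    consistent = (i - 1) <= amin <= (i + 2)
    return TiltZeroEstimate(theta0=float(theta0), grid_resolution=spacing,
                            phase_jump=float(jumps[i]), flip_found=True,
                            amplitude_min_consistent=bool(consistent))
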