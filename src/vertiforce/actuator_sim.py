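"""Coulomb-friction stick-slip dynamics of a shuttle-in-tube inertial positioner.

A friction-held shuttle rides inside a glass tube glued to a piezo stack.
During the slow ramp of an asymmetric sawtooth the shuttle sticks to the
tube and moves with it; during the rapid exponential deceleration the
required tangential force exceeds the static friction, the shuttle slips,
and it advances one net step per drive cycle.  Slip occurs when the rail
acceleration satisfies

    |a(t)| > Fs/m + g        (vertical; the gravity term drops horizontally)

The simulator is a discrete-time model at sampling rate ``fs``: rail
velocity and acceleration are finite differences of the sampled waveform,
and the slip gate is evaluated on that same discrete acceleration, so "zero
motion below threshold" holds exactly by construction while the per-cycle
displacement converges under fs refinement (the corner's velocity impulse
is fs-invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import STANDARD_GRAVITY


@dataclass(frozen=True)
class ActuatorConfig:
    """Shuttle mass, friction forces and mounting orientation."""

    shuttle_mass: float
    static_friction: float
    kinetic_friction: float
    orientation: str = "vertical"
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.shuttle_mass <= 0:
            raise ValueError("shuttle_mass must be positive")
        if not self.static_friction >= self.kinetic_friction >= 0:
            raise ValueError("need static_friction >= kinetic_friction >= 0")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError("orientation must be 'vertical' or 'horizontal'")
        if (self.orientation == "vertical"
                and self.static_friction <= self.shuttle_mass * self.gravity):
            warnings.warn(
                "static friction does not exceed the shuttle's weight: a "
                "vertical shuttle will not hold position at rest",
                stacklevel=2,
            )

    @property
    def g_component(self) -> float:
        """Gravity component along the motion axis (m/s^2)."""
        return self.gravity if self.orientation == "vertical" else 0.0


@dataclass(frozen=True)
class SawtoothWaveform:
    """Asymmetric sawtooth: linear ramp, then exponential decay back to zero.

    Per cycle ``u(t) = u_max * t/t_r`` for ``0 <= t < t_r`` and
    ``u(t) = u_max * exp(-(t - t_r)/tau_d)`` afterwards; the period must
    leave at least seven decay constants so each cycle ends near zero.
    """

    amplitude: float
    ramp_time: float
    decay_constant: float
    period: float
    n_cycles: int = 1
    polarity: int = 1

    def __post_init__(self) -> None:
        if min(self.ramp_time, self.decay_constant, self.period) <= 0:
            raise ValueError("all waveform times must be positive")
        if self.period < self.ramp_time + 7 * self.decay_constant:
            raise ValueError("period must be >= ramp_time + 7*decay_constant")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


def make_waveform(w: SawtoothWaveform, fs: float) -> np.ndarray:
    """Sampled rail displacement (m) over ``n_cycles`` periods."""
    if fs * w.decay_constant < 20:
        raise ValueError("fs too low: need fs*decay_constant >= 20 to "
                         "resolve the fast phase")
    n_per = int(round(w.period * fs))
    t = np.arange(n_per) / fs
    u = np.where(
        t < w.ramp_time,
        w.amplitude * t / w.ramp_time,
        w.amplitude * np.exp(-(t - w.ramp_time) / w.decay_constant),
    )
    return w.polarity * np.tile(u, w.n_cycles)


def peak_decay_acceleration(w: SawtoothWaveform) -> float:
    """Closed-form peak |acceleration| of the smooth decay phase.

    The exponential ``u_max * exp(-(t-t_r)/tau_d)`` has its largest second
    derivative ``u_max / tau_d**2`` at the start of the decay.  The
    ramp/decay corner itself carries a velocity discontinuity whose discrete
    acceleration grows with fs; see :func:`simulate_stick_slip`.
    """
    return w.amplitude / w.decay_constant**2


def slip_threshold(cfg: ActuatorConfig) -> float:
    """Rail acceleration above which stick cannot hold (m/s^2).

    ``Fs/m + g`` for a vertical shuttle, ``Fs/m`` horizontally — the
    conservative envelope over both slip directions.
    """
    return cfg.static_friction / cfg.shuttle_mass + cfg.g_component


@dataclass
class ActuatorTrace:
    """Rail and shuttle trajectories with a per-sample slip flag."""

    fs: float
    rail_position: np.ndarray
    shuttle_position: np.ndarray
    slip_mask: np.ndarray
    cycle_displacements: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.rail_position) == len(self.shuttle_position)
                == len(self.slip_mask)):
            raise ValueError("trace arrays must share one length")

    @property
    def net_displacement(self) -> float:
        return float(self.shuttle_position[-1] - self.shuttle_position[0])


def simulate_stick_slip(cfg: ActuatorConfig, w: SawtoothWaveform, fs: float | None = None) -> ActuatorTrace:
    """Integrate the Coulomb stick-slip model over the drive waveform.

    In stick the shuttle moves with the rail; stick breaks at sample ``i``
    when the force needed to follow, ``m*(a_rail[i] + g)``, exceeds the
    static friction.  In slip the shuttle obeys
    ``m*x'' = -Fk*sign(v_rel) - m*g`` (semi-implicit Euler at ``fs``) and
    re-sticks when the relative velocity crosses zero while the holding
    condition is satisfied.  Default ``fs = 50/decay_constant``.
    """
    if fs is None:
        fs = 50.0 / w.decay_constant
    rail = make_waveform(w, fs)
    dt = 1.0 / fs
    n = rail.size
    v_rail = np.empty(n)
    v_rail[0] = 0.0
    v_rail[1:] = np.diff(rail) / dt
    a_rail = np.empty(n)
    a_rail[:2] = 0.0
    a_rail[2:] = np.diff(v_rail[1:]) / dt

    g = cfg.g_component
    m = cfg.shuttle_mass
    fs_max = cfg.static_friction
    fk = cfg.kinetic_friction

    x = np.empty(n)
    slip_mask = np.zeros(n, dtype=bool)
    x[0] = rail[0]
    v_sh = 0.0
    sticking = True
    offset = 0.0  # shuttle - rail while sticking

    for i in range(1, n):
        if sticking:
            required = m * (a_rail[i] + g)
            if abs(required) > fs_max:
                sticking = False
                v_sh = v_rail[i - 1]  # shuttle keeps its pre-break velocity
            else:
                x[i] = rail[i] + offset
                continue
        # slip dynamics
        v_rel = v_sh - v_rail[i]
        acc = -fk / m * np.sign(v_rel) - g
        v_sh_new = v_sh + acc * dt
        v_rel_new = v_sh_new - v_rail[i]
        if v_rel_new * v_rel <= 0.0:
            # relative velocity crossed zero within this step: try to re-stick
            if abs(m * (a_rail[i] + g)) <= fs_max:
                sticking = True
                v_sh = v_rail[i]
                # land proportionally at the crossing point
                frac = abs(v_rel) / max(abs(v_rel) + abs(v_rel_new), 1e-300)
                x[i] = x[i - 1] + (v_sh + acc * frac * dt * 0.5) * dt
                offset = x[i] - rail[i]
                slip_mask[i] = True  # landing step still carries relative motion
                continue
        v_sh = v_sh_new
        x[i] = x[i - 1] + v_sh * dt
        slip_mask[i] = True

    n_per = int(round(w.period * fs))
    starts = np.arange(w.n_cycles) * n_per
    ends = np.minimum(starts + n_per - 1, n - 1)
    cyc = x[ends] - x[starts]
    return ActuatorTrace(fs=fs, rail_position=rail, shuttle_position=x,
                         slip_mask=slip_mask, cycle_displacements=cyc)
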