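"""Stick-slip actuator: waveform closed forms, slip gate, and dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vertiforce import (
    ActuatorConfig,
    SawtoothWaveform,
    make_waveform,
    peak_decay_acceleration,
    simulate_stick_slip,
    slip_threshold,
)

WAVE = dict(amplitude=100e-9, ramp_time=1e-3, decay_constant=20e-6,
            period=1e-3 + 10 * 20e-6)
CFG = dict(shuttle_mass=0.7e-3, static_friction=0.02, kinetic_friction=0.015)


class TestWaveform:
    def test_boundary_values(self):
        w = SawtoothWaveform(**WAVE)
        fs = 50 / w.decay_constant
        u = make_waveform(w, fs)
        assert u[0] == 0.0
        i_r = int(round(w.ramp_time * fs))
        assert u[i_r - 1] == pytest.approx(w.amplitude, rel=1e-3)

    def test_polarity_mirrors_waveform(self):
        w_pos = SawtoothWaveform(**WAVE)
        w_neg = SawtoothWaveform(**WAVE, polarity=-1)
        fs = 50 / w_pos.decay_constant
        np.testing.assert_array_equal(make_waveform(w_neg, fs),
                                      -make_waveform(w_pos, fs))

    def test_peak_decay_acceleration_closed_form(self):
        w = SawtoothWaveform(**WAVE)
        assert peak_decay_acceleration(w) == pytest.approx(
            w.amplitude / w.decay_constant**2)
        # numeric second derivative of the decay agrees
        fs = 2000 / w.decay_constant
        u = make_waveform(w, fs)
        i_r = int(round(w.ramp_time * fs))
        a = np.diff(u, 2) * fs**2
        decay_zone = a[i_r + 5:i_r + 50]
        assert np.max(np.abs(decay_zone)) == pytest.approx(
            peak_decay_acceleration(w), rel=0.05)

    def test_invalid_period_rejected(self):
        with pytest.raises(ValueError):
            SawtoothWaveform(amplitude=1e-7, ramp_time=1e-3,
                             decay_constant=1e-3, period=2e-3)

    def test_underresolved_fs_rejected(self):
        w = SawtoothWaveform(**WAVE)
        with pytest.raises(ValueError):
            make_waveform(w, 5 / w.decay_constant)


class TestSlipThreshold:
    def test_zero_friction_horizontal_slips_at_any_acceleration(self):
        cfg = ActuatorConfig(shuttle_mass=1e-3, static_friction=0.0,
                             kinetic_friction=0.0, orientation="horizontal")
        assert slip_threshold(cfg) == 0.0

    def test_printed_arithmetic(self):
        cfg = ActuatorConfig(**CFG, orientation="vertical")
        assert slip_threshold(cfg) == pytest.approx(0.02 / 0.0007 + 9.81, rel=1e-6)
        assert slip_threshold(cfg) == pytest.approx(38.38, abs=0.01)

    @given(m=st.floats(1e-4, 1e-2), fs_=st.floats(1e-3, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_vertical_minus_horizontal_is_g(self, m, fs_):
        v = ActuatorConfig(shuttle_mass=m, static_friction=fs_,
                           kinetic_friction=fs_ / 2, orientation="vertical")
        h = ActuatorConfig(shuttle_mass=m, static_friction=fs_,
                           kinetic_friction=fs_ / 2, orientation="horizontal")
        assert slip_threshold(v) - slip_threshold(h) == pytest.approx(9.81)


class TestStickSlip:
    def test_subthreshold_waveform_gives_zero_net_motion(self):
        cfg = ActuatorConfig(**CFG, orientation="vertical")
        gentle = SawtoothWaveform(amplitude=1e-12, ramp_time=1e-3,
                                  decay_constant=20e-6,
                                  period=1e-3 + 10 * 20e-6, n_cycles=3)
        tr = simulate_stick_slip(cfg, gentle)
        fs = tr.fs
        a_peak = np.max(np.abs(np.diff(tr.rail_position, 2))) * fs**2
        assert a_peak <= slip_threshold(cfg)
        assert not tr.slip_mask.any()
        assert tr.net_displacement == pytest.approx(0.0, abs=1e-15)

    @given(umax=st.floats(1e-13, 1e-11), mass=st.floats(1e-4, 5e-3))
    @settings(max_examples=15, deadline=None)
    def test_slip_gate_property_horizontal(self, umax, mass):
        """No slip ever occurs when the discrete rail acceleration stays
        below the slip threshold (horizontal: threshold is exactly Fs/m)."""
        cfg = ActuatorConfig(shuttle_mass=mass, static_friction=0.05,
                             kinetic_friction=0.02, orientation="horizontal")
        w = SawtoothWaveform(amplitude=umax, ramp_time=1e-3,
                             decay_constant=50e-6, period=1e-3 + 10 * 50e-6,
                             n_cycles=2)
        tr = simulate_stick_slip(cfg, w)
        a_peak = np.max(np.abs(np.diff(tr.rail_position, 2))) * tr.fs**2
        if a_peak <= slip_threshold(cfg):
            assert not tr.slip_mask.any()
            assert tr.net_displacement == pytest.approx(0.0, abs=1e-15)

    def test_slip_gate_vertical_tight_and_envelope_bounds(self):
        """Vertically, gravity makes the break asymmetric: no slip while
        m*|a+g| <= Fs, and the printed envelope Fs/m + g is conservative —
        any waveform whose peak acceleration exceeds it does slip."""
        cfg = ActuatorConfig(**CFG, orientation="vertical")
        w = SawtoothWaveform(**WAVE, n_cycles=2)
        tr = simulate_stick_slip(cfg, w)
        a = np.diff(tr.rail_position, 2) * tr.fs**2
        assert np.max(np.abs(a + 9.81)) * cfg.shuttle_mass > cfg.static_friction
        assert np.max(np.abs(a)) > slip_threshold(cfg)
        assert tr.slip_mask.any()

    def test_shuttle_moves_with_rail_while_sticking(self):
        cfg = ActuatorConfig(**CFG, orientation="vertical")
        tr = simulate_stick_slip(cfg, SawtoothWaveform(**WAVE, n_cycles=3))
        stick = ~tr.slip_mask[1:]
        np.testing.assert_allclose(np.diff(tr.shuttle_position)[stick],
                                   np.diff(tr.rail_position)[stick], atol=1e-18)

    def test_mirrored_waveform_negates_horizontal_displacement(self):
        cfg = ActuatorConfig(**CFG, orientation="horizontal")
        pos = simulate_stick_slip(cfg, SawtoothWaveform(**WAVE, n_cycles=3))
        neg = simulate_stick_slip(cfg, SawtoothWaveform(**WAVE, n_cycles=3,
                                                        polarity=-1))
        np.testing.assert_allclose(neg.cycle_displacements,
                                   -pos.cycle_displacements, rtol=1e-9)

    def test_displacement_nondecreasing_in_amplitude(self):
        cfg = ActuatorConfig(**CFG, orientation="horizontal")
        prev = -np.inf
        for umax in np.linspace(50e-9, 500e-9, 6):
            w = SawtoothWaveform(amplitude=umax, ramp_time=1e-3,
                                 decay_constant=20e-6,
                                 period=1e-3 + 10 * 20e-6, n_cycles=2)
            d = float(np.mean(simulate_stick_slip(cfg, w).cycle_displacements))
            assert d >= prev - 1e-15
            assert d > 0
            prev = d

    def test_fs_refinement_convergence(self):
        cfg = ActuatorConfig(**CFG, orientation="vertical")
        w = SawtoothWaveform(**WAVE, n_cycles=3)
        base_fs = 100 / w.decay_constant
        d1 = np.mean(simulate_stick_slip(cfg, w, base_fs).cycle_displacements)
        d2 = np.mean(simulate_stick_slip(cfg, w, 2 * base_fs).cycle_displacements)
        assert d2 == pytest.approx(d1, rel=0.02)

    def test_vertical_hold_warning_when_friction_insufficient(self):
        with pytest.warns(UserWarning):
            ActuatorConfig(shuttle_mass=0.7e-3, static_friction=1e-4,
                           kinetic_friction=1e-5, orientation="vertical")
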