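"""Statistical and deterministic behaviour of the cantilever simulators."""

import numpy as np
import pytest

from vertiforce import (
    BOLTZMANN,
    CantileverModel,
    DetectionModel,
    DriftModel,
    ModulationSchedule,
    generate_staircase,
    lockin,
    min_stiffness_factor,
    simulate_raster_scan,
    simulate_sum_signal,
    simulate_tip_trace,
)

FS = 48_000.0


class TestTipTrace:
    def test_zero_temperature_zero_noise_is_fixed_point(self):
        m = CantileverModel(stiffness=1e-5, correlation_time=0.125e-3,
                            temperature=0.0)
        tr = simulate_tip_trace(m, duration=0.01, fs=FS, seed=0)
        assert np.all(tr.samples == 0.0)

    def test_deterministic_relaxation_to_force_over_stiffness(self):
        m = CantileverModel(stiffness=1e-5, correlation_time=0.125e-3,
                            temperature=0.0)
        sched = ModulationSchedule(frequency=0.5, duty=0.99, force_on=5e-15)
        tr = simulate_tip_trace(m, modulation=sched, duration=1.0, fs=FS, seed=0)
        assert tr.samples[-1] == pytest.approx(5e-15 / 1e-5, rel=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_equipartition_variance(self, reference_model, seed):
        tr = simulate_tip_trace(reference_model, duration=60.0, fs=FS, seed=seed)
        expected = BOLTZMANN * 295.0 / 5.19e-6
        assert tr.samples.var() == pytest.approx(expected, rel=0.05)

    def test_autocorrelation_at_lag_tau(self, reference_model):
        tr = simulate_tip_trace(reference_model, duration=30.0, fs=FS, seed=7)
        lag = round(reference_model.correlation_time * FS)  # exactly tau
        x = tr.samples - tr.samples.mean()
        rho = np.dot(x[:-lag], x[lag:]) / np.dot(x, x)
        assert rho == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_statistics_invariant_under_fs_refinement(self, reference_model):
        v1 = simulate_tip_trace(reference_model, duration=20.0, fs=FS,
                                seed=11).samples.var()
        v2 = simulate_tip_trace(reference_model, duration=20.0, fs=2 * FS,
                                seed=12).samples.var()
        assert v1 == pytest.approx(v2, rel=0.05)

    @pytest.mark.parametrize("force", [0.1e-15, 1e-15, 10e-15])
    def test_mean_under_constant_force_is_force_over_k(self, reference_model, force):
        sched = ModulationSchedule(frequency=1.0, duty=0.999, force_on=force,
                                   force_off=force)
        tr = simulate_tip_trace(reference_model, modulation=sched,
                                duration=30.0, fs=FS, seed=int(force * 1e16))
        expected = force / reference_model.stiffness
        sem = np.sqrt(reference_model.thermal_variance
                      * 2 * reference_model.correlation_time / 30.0)
        assert abs(tr.samples.mean() - expected) < 4 * sem

    def test_identical_seed_identical_trace(self, reference_model):
        a = simulate_tip_trace(reference_model, duration=0.5, fs=FS, seed=42)
        b = simulate_tip_trace(reference_model, duration=0.5, fs=FS, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_drift_ramp_and_readout_noise_are_added(self, reference_model):
        tr = simulate_tip_trace(
            reference_model,
            DetectionModel(noise_sd=1e-9),
            drift=DriftModel(velocity=1e-9),
            duration=10.0, fs=1000.0, seed=5)
        # ramp dominates the trace trend
        t = tr.times()
        slope = np.polyfit(t, tr.samples, 1)[0]
        assert slope == pytest.approx(1e-9, rel=0.2)

    def test_invalid_arguments_rejected(self, reference_model):
        with pytest.raises(ValueError):
            simulate_tip_trace(reference_model, duration=-1.0, fs=FS, seed=0)
        with pytest.raises(ValueError):
            simulate_tip_trace(reference_model, duration=1.0, fs=0.0, seed=0)
        with pytest.raises(ValueError):
            CantileverModel(stiffness=-1e-6, correlation_time=1e-4)

    def test_mod_state_filled_from_schedule(self, reference_model):
        sched = ModulationSchedule(frequency=2.0, duty=0.5, force_on=1e-15)
        tr = simulate_tip_trace(reference_model, modulation=sched,
                                duration=1.0, fs=1000.0, seed=0)
        assert tr.mod_state is not None
        # duty 0.5 at 2 Hz over 1 s: half the samples on
        assert abs(int((tr.mod_state == 1).sum()) - 500) <= 2


class TestSumSignal:
    KW = dict(drive_freq=1000.0, drive_amp=5e-9, duration=0.05, fs=FS,
              noise_frac=0.0, seed=0)

    def test_zero_tilt_constant_signal(self):
        tr = simulate_sum_signal(0.0, **self.KW)
        assert np.ptp(tr.samples) == 0.0
        r, _ = lockin(tr, 1000.0)
        assert r == pytest.approx(0.0, abs=1e-15)

    def test_opposite_tilts_flip_phase_by_180(self):
        _, p_neg = lockin(simulate_sum_signal(-5.0, **self.KW), 1000.0)
        _, p_pos = lockin(simulate_sum_signal(+5.0, **self.KW), 1000.0)
        diff = (p_pos - p_neg + 180.0) % 360.0 - 180.0
        assert abs(abs(diff) - 180.0) < 1e-6

    def test_small_amplitude_ratio_follows_sine(self):
        a1, _ = lockin(simulate_sum_signal(1.0, **self.KW), 1000.0)
        a2, _ = lockin(simulate_sum_signal(2.0, **self.KW), 1000.0)
        expected = np.sin(np.deg2rad(2.0)) / np.sin(np.deg2rad(1.0))
        assert a2 / a1 == pytest.approx(expected, rel=1e-3)

    def test_amplitude_even_phase_odd_in_tilt(self):
        for theta in (1.0, 3.0, 7.5):
            ap, pp = lockin(simulate_sum_signal(+theta, **self.KW), 1000.0)
            am, pm = lockin(simulate_sum_signal(-theta, **self.KW), 1000.0)
            assert ap == pytest.approx(am, rel=1e-9)
            d = (pp - pm + 180.0) % 360.0 - 180.0
            assert abs(abs(d) - 180.0) < 1e-6

    def test_out_of_range_tilt_rejected(self):
        with pytest.raises(ValueError):
            simulate_sum_signal(95.0, **self.KW)


class TestRasterScan:
    def test_identity_coupling_measured_equals_commanded(self):
        scan = simulate_raster_scan(0.0, 0.0, n_lines=4, line_length=1e-6)
        assert np.array_equal(scan.meas_x, scan.cmd_x)
        assert np.array_equal(scan.meas_y, scan.cmd_y)

    def test_linear_map_exact_without_noise(self):
        scan = simulate_raster_scan(0.0, 0.02, n_lines=4, line_length=1e-6)
        np.testing.assert_allclose(scan.meas_y - scan.cmd_y, 0.02 * scan.cmd_x,
                                   atol=1e-20)

    def test_regression_recovers_coupling_under_noise(self):
        scan = simulate_raster_scan(0.0, 0.02, n_lines=20, line_length=1e-6,
                                    noise_sd=0.0005e-6, seed=3)
        slopes = []
        for j in range(scan.n_lines):
            m = scan.line_index == j
            slopes.append(np.polyfit(scan.meas_x[m], scan.meas_y[m], 1)[0])
        assert np.mean(slopes) == pytest.approx(0.02, abs=0.001)

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            simulate_raster_scan(0.0, 0.0, n_lines=1, line_length=1e-6)


class TestStaircase:
    def test_single_step_noiseless_single_level_change(self):
        trace, steps = generate_staircase(1, mean_step=3e-9, sd_step=0.0,
                                          dwell=0.1, fs=100.0, direction="up",
                                          seed=0)
        changes = np.nonzero(np.diff(trace.samples))[0]
        assert changes.size == 1
        assert trace.samples[-1] - trace.samples[0] == pytest.approx(steps[0])

    def test_deterministic_steps_sum_exactly(self):
        trace, _ = generate_staircase(10, mean_step=3e-9, sd_step=0.0,
                                      dwell=0.1, fs=100.0, direction="up",
                                      seed=0)
        assert trace.samples[-1] - trace.samples[0] == pytest.approx(30e-9, rel=1e-12)

    def test_step_mean_obeys_clt(self):
        _, steps = generate_staircase(200, mean_step=2.79e-9, sd_step=0.52e-9,
                                      dwell=0.05, fs=100.0, direction="down",
                                      seed=4)
        sem = 0.52e-9 / np.sqrt(200)
        assert abs(abs(steps.mean()) - 2.79e-9) < 3 * sem

    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            generate_staircase(0, mean_step=1e-9, sd_step=0.0, dwell=0.1,
                               fs=100.0)


@pytest.mark.parametrize("theta,expected", [(0.0, 0.0), (45.0, 0.5), (90.0, 1.0)])
def test_min_stiffness_factor_closed_form(theta, expected):
    assert min_stiffness_factor(theta) == pytest.approx(expected, abs=1e-12)


def test_min_stiffness_factor_monotone_and_bounded():
    thetas = np.linspace(0.0, 90.0, 91)
    vals = np.array([min_stiffness_factor(t) for t in thetas])
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(ValueError):
        min_stiffness_factor(-1.0)
    with pytest.raises(ValueError):
        min_stiffness_factor(91.0)
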