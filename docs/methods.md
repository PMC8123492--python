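# Methods

This note documents the physical models, estimators and numerical choices
behind `vertiforce`, and what the synthetic-data generators do and do not
emulate.

## Cantilever thermal dynamics

An ultra-compliant cantilever mounted vertically senses in-plane forces
through the displacement of its tip. The tip coordinate `x` is modelled as
an overdamped harmonically bound Brownian particle (Ornstein–Uhlenbeck
process):

    dx = -(x - F(t)/k)/tau dt + sqrt(2 kB T/(k tau)) dW

with spring constant `k` (N/m), correlation time `tau = gamma/k` (s), drag
`gamma` (kg/s) and bath temperature `T` (K). Stationary statistics:
variance `kB T/k` (equipartition), autocorrelation `exp(-|dt|/tau)`,
one-sided power spectral density

    S(f) = kB T / (pi^2 gamma (fc^2 + f^2)),   fc = 1/(2 pi tau) = k/(2 pi gamma).

`simulate_tip_trace` uses the *exact* discretization — decay factor
`exp(-dt/tau)`, innovation variance `(kB T/k)(1 - exp(-2 dt/tau))` — so all
of the above hold at any sampling rate, not just asymptotically. The
recursion is evaluated with a single-pole IIR filter, which keeps
multi-minute traces at 48 kHz below a second of compute.

Key defaults, with reasons:

| parameter | default | why |
|---|---|---|
| stiffness `k` | 5.19e-6 N/m | back-computed from the published force/shift pair (2.7 fN / 0.52 nm); inside the 1e-6–1e-5 N/m probe range |
| correlation time `tau` | 0.125 ms | the published autocorrelation time; `tau` is the canonical noise input, `gamma = k*tau` derived |
| temperature `T` | 295 K | room temperature; never printed by the instrument's description, so stated here as an assumption |
| sampling rate | 48 kHz | the instrument's acquisition rate |
| evanescent decay length `d` | 150 nm | near-field decay scale of the detection system |

The applied force is treated as quasi-static: it enters the OU mean
`F(t)/k` instantaneously. This is justified because the modulation period
(1 s) exceeds `tau` (0.125 ms) by four orders of magnitude; the transient
after each toggle lasts a few `tau` and is discarded by the pipeline anyway.
Readout noise is additive white Gaussian on position (the real detector's
noise spectrum is not characterised; white is the neutral choice). Drift is
a linear ramp plus optional white noise.

What the generator does *not* emulate: hydrodynamic frequency-dependent
drag, higher cantilever modes, detector nonlinearity, laser-intensity
fluctuations (the published long-run force-resolution limit), and
low-frequency 1/f mechanical noise. Passing recovery tests therefore
demonstrates the correctness of the estimators under the stated model, not
robustness to every artefact of real instrument data.

## Spring-constant calibration

`estimate_psd` is a Welch averaged periodogram (Hann window, 50 % overlap,
default segment 4096 samples), one-sided, DC bin excluded downstream.
`fit_lorentzian` performs least squares on log-power over log-spaced
frequency bins (default 60), which equalises the weight of each frequency
decade and tames the chi-squared scatter of periodogram ordinates. Default
fit range is `[fc/10, min(10 fc, 0.8 f_Nyquist)]`, with `fc` guessed from
the half-power point. The stiffness is `k = 2 pi fc gamma`, enforced as an
identity on the result object; standard errors propagate from the
log-parameter covariance including the fc–gamma covariance term.

Aliasing: when the corner frequency is only ~19x below Nyquist (fs·tau = 6
at the operating point), the folded Lorentzian tail biases the plain fit by
about −3 % in `k`. The exactly sampled OU process is an AR(1) sequence
whose one-sided spectrum is closed-form (`sampled_ou_psd`); passing
`sampling_rate` to `fit_lorentzian` fits that model instead and removes the
bias (residual ±0.3 % at 60 s in our checks). The plain Lorentzian remains
the default — it is the continuous model and the right choice for externally
supplied spectra — while trace-based workflows (the fig6 scenario,
`stiffness_distribution(correct_aliasing=True)`) use the sampled model.
A white readout-noise floor is not modelled in the fit; the default range
ends well before a realistic floor dominates.

`stiffness_distribution` repeats PSD + fit over traces, excludes and logs
failures, and flags distributions whose max/min ratio exceeds 2 (a mixture
of probes, e.g. 1e-6 and 1e-5 N/m, trips this). With a single trace the
distribution SD falls back to the fit's own standard error.

## Intermittent-mode force inference

The pipeline measures femtonewton forces by toggling them with a 1 Hz
square wave and differencing the on/off position distributions:

1. **Decimate** by `max(1, ceil(tau * fs))` (= 6 at 48 kHz, 0.125 ms) so
   retained samples are ~one correlation time apart. `ceil` is chosen so
   the spacing never falls below `tau`.
2. **Split** by the modulation schedule, discarding a settling window
   (default `5 tau`) after each toggle; those samples are labelled
   `transition`.
3. **Shift**: `dx = mean(on) - mean(off)`, with standard error
   `sqrt(var(on)/n_on + var(off)/n_off)` treating post-decimation samples
   as independent. At spacing exactly `tau` the residual lag-1 correlation
   is `e^-1`, so this SE underestimates the true estimator scatter by a
   factor of ~1.5; tolerances that use `3 SE` absorb this, and the
   limitation is stated here deliberately rather than silently corrected,
   matching how such pipelines are conventionally run.
4. **Force**: `F = k_mean * dx` exactly, with the standard two-term
   first-order propagation
   `sigma_F = sqrt(k_mean^2 sigma_dx^2 + dx^2 sigma_k^2)` (no printed
   formula exists; independence of the two errors is assumed).

`accumulate` composes the stages and additionally returns per-cycle shifts
and the SEM-versus-accumulation-time curve (SEM shrinks like `1/sqrt(t)`;
one minute of cycling at the operating point is already sub-femtonewton).
An optional per-cycle detrend (`detrend_cycles=True`, default off) removes
the per-cycle baseline before differencing, trading one degree of freedom
per cycle for drift immunity. Gaussianity of the two distributions is
reported (skewness/kurtosis in `distribution_summary`), not enforced.

## Tilt-zero alignment

A tilted probe driven acoustically (modelled as a pure forced sinusoid —
the drive is deliberately off-resonance, so no resonance dynamics are
included) oscillates vertically by `drive_amp * sin(theta)`; the
evanescent readout transduces this exponentially, so the demodulated
fundamental amplitude is proportional to `|sin(theta)|` and its phase
reverses by 180° through vertical. `lockin` demodulates over whole
reference periods with the convention `phi = 0` for a pure sine.

`find_vertical` locates the adjacent angle pair whose circular phase change
exceeds 90° (and is closest to 180°), requires the amplitude minimum to lie
within one grid point of that pair, and returns the pair midpoint. The
midpoint is used rather than a parabolic interpolation of the amplitude
because `|sin(theta)|` has a cusp, not a parabola, at zero. Phases are
always compared on the circle (shortest arc) to avoid branch-cut
artefacts. Multiple phase reversals raise an error (the sweep is too noisy
to trust); none at all returns `flip_found=False`.

Monte-Carlo sweeps use `synthesize_tilt_response`, which applies the
5 % multiplicative amplitude noise and 10° phase noise directly to the
demodulated quantities — these are lock-in-output noise figures, so
injecting them post-demodulation is both faithful and cheap. The drive
frequency (1 kHz) and amplitude (5 nm) are unpublished; they are exposed
as parameters and their exact values are immaterial to the routine.

## Stick-slip positioner

The shuttle-in-tube coarse positioner is modelled with Coulomb friction:
static `Fs`, kinetic `Fk <= Fs` (richer stiction models — Stribeck,
presliding — are out of scope). In stick the shuttle follows the rail; the
stick breaks when the required tangential force `m (a_rail + g)` exceeds
`Fs` (gravity signed physically; the printed envelope `|a| > Fs/m + g` is
the conservative bound over both directions and is exposed as
`slip_threshold`). In slip, `m x'' = -Fk sign(v_rel) - m g`, integrated
semi-implicitly; re-stick occurs when the relative velocity crosses zero
under a holding-compatible rail acceleration.

The drive waveform is a slow linear ramp (`u_max t/t_r`) followed by an
exponential decay (`u_max exp(-(t-t_r)/tau_d)`), the shape that steps most
consistently in practice. Its velocity is discontinuous at the ramp/decay
corner, so the *instantaneous* analytic acceleration is undefined there;
the simulator is therefore defined as a discrete-time model at sampling
rate `fs` (default `50/tau_d`): rail kinematics are finite differences of
the sampled waveform and the slip gate is evaluated on the same discrete
acceleration. The corner's velocity impulse is independent of `fs`, so the
per-cycle displacement converges under refinement (<2 % on doubling at the
default rate), while the smooth decay-phase peak acceleration
`u_max/tau_d^2` is available in closed form (`peak_decay_acceleration`).
The absolute step size of the real hardware (2.79 nm) is a calibration
fact, not derivable from this model; the staircase generator takes it as an
input statistic.

## Stage metrology

**Steps** — two-window sliding mean difference: statistic
`mean(x[i:i+w]) - mean(x[i-w:i])`, threshold `5 sigma * sqrt(2/w)` with the
noise SD estimated robustly from successive differences (median/1.349 of
|diff|/sqrt 2); one detection per above-threshold run at the extremum;
detections closer than `min_dwell` merged keeping the larger statistic;
sizes are plateau-mean differences clipped at neighbouring steps. The
detector is offset- and translation-invariant by construction. No
segmentation algorithm is published for the real step records; this
detector is a stated stand-in, and change-point alternatives can be swapped
behind the same interface.

**Drift** — OLS slope of position on time. Because stage noise is
correlated, the naive SE is inflated by `sqrt(n/n_eff)` with
`n_eff = n/ceil(tau_est * fs)` and `tau_est = -1/ln(rho_1)` from the lag-1
residual autocorrelation. This effective-sample-size correction was chosen
over a block bootstrap for determinism and testability. Published drift
uncertainties are treated as 1-sigma values.

**Cross-talk** — constant linear coupling matrix between scan axes (a
linear correction sufficed on the real instrument, so higher-order coupling
is out of scope). Within a raster line the slow-axis command is constant,
so the per-line regression slope of measured-slow on measured-fast is the
coupling; slopes are pooled across lines. Only the fast→slow coefficient is
identifiable from one raster (the reverse has no within-line signal); the
transposed scan gives the other. Re-estimating the residual on the *same*
scan after correction returns zero identically (the pooled slope of its own
residuals), so the recovery scenario applies the fitted correction to an
independent validation scan and reports the residual coupling measured
there.

## Randomness and determinism

Every generator takes one explicit integer seed and creates its own
`numpy.random.default_rng`; there is no hidden global state. Identical
seeds give identical traces and byte-identical scenario reports (reports
carry the package version, a SHA-1 config hash and the seed). Scenario
batteries derive child seeds from a master seed via `SeedSequence`.

## Problem sizes

The recovery scenarios run at the instrument's published protocol sizes:
16 minutes at 48 kHz (~46 M samples) for the force recovery, 100 sweeps for
the tilt Monte Carlo, 200 steps, 30 minutes at 10 Hz for drift, 20 raster
lines. Unit tests use shorter traces (seconds to one minute) of the same
physics; the repetition-unbiasedness check runs 20 repetitions of 15 s,
which tests the same CLT property as longer protocols at lower cost.

## Known limitations

- Post-decimation samples retain `e^-1` lag-1 correlation (see above); the
  reported shift SE is accordingly ~1.5x optimistic.
- The PSD fit ignores any readout-noise floor; traces dominated by white
  readout noise above `fc` will bias `gamma` low unless the fit range is
  restricted manually.
- The stick-slip model has no piezo hysteresis/creep, tube flexure or
  viscoelastic pad dynamics; absolute step sizes are inputs, not outputs.
- The drift estimator assumes a single AR(1)-like noise scale; strongly
  multi-scale noise will leave its SE optimistic.
- CSV trace round-trips are exact to the 12-significant-digit column
  format (~1e-11 nm at tens-of-nm amplitudes); the HDF5 container is
  bit-exact.
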