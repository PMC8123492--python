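"""Spring-constant calibration from the thermal power spectrum.

The position power spectral density of an overdamped harmonically bound
probe is the one-sided Lorentzian

    S_x(f) = kB * T / (pi^2 * gamma * (fc^2 + f^2)),

whose corner frequency ``fc = k / (2 pi gamma)`` and drag ``gamma`` give
the stiffness through the identity ``k = 2 pi fc gamma``.  Integrating the
model over all positive frequencies recovers equipartition,
``kB*T/k`` — the two constraints that pin the spectral form down.

The fit is least squares on log-power over log-spaced frequency bins, which
tames the chi^2_2 scatter of averaged periodograms and weights each decade
of frequency evenly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .constants import BOLTZMANN
from .trace import PositionTrace


class FitError(RuntimeError):
    """Raised when a spectral fit fails to converge or has no usable data."""


@dataclass
class PSDEstimate:
    """One-sided averaged-periodogram PSD (m^2/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray
    n_segments: int
    segment_length: int
    window_name: str

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] < 0:
            raise ValueError("frequencies must be non-negative and strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def integral(self) -> float:
        """Riemann integral of the PSD, m^2 (≈ trace variance, Parseval)."""
        df = self.frequencies[1] - self.frequencies[0]
        return float(np.sum(self.power) * df)


@dataclass
class LorentzianFit:
    """Lorentzian PSD fit result; ``stiffness = 2*pi*fc*gamma`` by construction."""

    fc: float
    gamma: float
    fc_se: float
    gamma_se: float
    stiffness_se: float
    fit_range: tuple[float, float]
    goodness: float
    at_boundary: bool = False
    stiffness: float = field(init=False)

    def __post_init__(self) -> None:
        if self.fc <= 0 or self.gamma <= 0:
            raise ValueError("fc and gamma must be positive")
        self.stiffness = 2.0 * np.pi * self.fc * self.gamma

    def model(self, f: np.ndarray, temperature: float) -> np.ndarray:
        return lorentzian_psd(f, self.fc, self.gamma, temperature)


@dataclass
class StiffnessDistribution:
    """Collection of stiffness estimates from repeated calibrations."""

    values: np.ndarray
    mean: float
    sd: float
    n: int
    range_flag: bool = False
    failures: list = field(default_factory=list)

    @classmethod
    def from_values(cls, values, single_fit_se: float | None = None,
                    failures: list | None = None) -> "StiffnessDistribution":
        values = np.asarray(values, dtype=float)
        if values.size < 1:
            raise ValueError("need at least one stiffness value")
        if values.size == 1:
            # degenerate aggregation: report the fit's own uncertainty as sd
            sd = float(single_fit_se) if single_fit_se is not None else 0.0
        else:
            sd = float(np.std(values, ddof=1))
        # decade-scale spread check: a mixture of probes shows up here
        range_flag = bool(values.max() / values.min() > 2.0)
        return cls(values=values, mean=float(values.mean()), sd=sd,
                   n=int(values.size), range_flag=range_flag,
                   failures=failures or [])


def lorentzian_psd(f: np.ndarray, fc: float, gamma: float,
                   temperature: float) -> np.ndarray:
    """One-sided thermal Lorentzian S(f) = kB*T / (pi^2 * gamma * (fc^2 + f^2))."""
    f = np.asarray(f, dtype=float)
    return BOLTZMANN * temperature / (np.pi**2 * gamma * (fc**2 + f**2))


def sampled_ou_psd(f: np.ndarray, fc: float, gamma: float, temperature: float,
                   fs: float) -> np.ndarray:
    """One-sided PSD of the exactly sampled OU process (aliasing included).

    A trace sampled at ``fs`` is an AR(1) sequence with pole
    ``a = exp(-2 pi fc / fs)``; its spectrum is the Lorentzian with all
    alias orders folded into [0, fs/2]:

        S(f) = (2 sigma^2 / fs) * (1 - a^2) / (1 - 2 a cos(2 pi f/fs) + a^2),

    ``sigma^2 = kB*T/k`` the equipartition variance.  Converges to
    :func:`lorentzian_psd` for ``fs >> fc``.
    """
    f = np.asarray(f, dtype=float)
    sigma2 = BOLTZMANN * temperature / (2.0 * np.pi * fc * gamma)
    a = np.exp(-2.0 * np.pi * fc / fs)
    return (2.0 * sigma2 / fs) * (1.0 - a * a) / (
        1.0 - 2.0 * a * np.cos(2.0 * np.pi * f / fs) + a * a)


def estimate_psd(trace: PositionTrace, segment_length: int | None = None,
                 window: str = "hann") -> PSDEstimate:
    """Averaged-periodogram (Welch, 50% overlap) one-sided PSD of a trace."""
    n = trace.n
    if segment_length is None:
        segment_length = min(4096, n)
    if segment_length > n:
        raise ValueError("segment_length exceeds trace length")
    freqs, power = signal.welch(
        trace.samples, fs=trace.fs, window=window, nperseg=segment_length,
        noverlap=segment_length // 2, detrend="constant", scaling="density",
    )
    n_segments = max(1, (n - segment_length // 2) // (segment_length // 2))
    return PSDEstimate(frequencies=freqs, power=power, n_segments=n_segments,
                       segment_length=segment_length, window_name=window)


def average_psds(psds: list[PSDEstimate]) -> PSDEstimate:
    """Average PSDs computed on a common frequency grid (e.g. per off-chunk)."""
    if not psds:
        raise ValueError("no PSDs to average")
    f0 = psds[0].frequencies
    for p in psds[1:]:
        if p.frequencies.shape != f0.shape or not np.allclose(p.frequencies, f0):
            raise ValueError("PSDs must share one frequency grid")
    power = np.mean([p.power for p in psds], axis=0)
    return PSDEstimate(frequencies=f0, power=power,
                       n_segments=sum(p.n_segments for p in psds),
                       segment_length=psds[0].segment_length,
                       window_name=psds[0].window_name)


def _log_bin(f: np.ndarray, p: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Average (f, p) into log-spaced frequency bins; empty bins dropped."""
    edges = np.geomspace(f[0], f[-1], n_bins + 1)
    idx = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, n_bins - 1)
    fb, pb = [], []
    for b in range(n_bins):
        m = idx == b
        if np.any(m):
            fb.append(np.exp(np.mean(np.log(f[m]))))
            pb.append(np.mean(p[m]))
    return np.array(fb), np.array(pb)


def _guess_fc(f: np.ndarray, p: np.ndarray) -> float:
    """Corner-frequency guess from the half-power point of the binned PSD."""
    fb, pb = _log_bin(f, p, 40)
    plateau = np.median(pb[: max(3, len(pb) // 8)])
    below = np.nonzero(pb < plateau / 2.0)[0]
    return float(fb[below[0]]) if below.size else float(fb[len(fb) // 2])


def fit_lorentzian(psd: PSDEstimate, temperature: float,
                   f_lo: float | None = None, f_hi: float | None = None,
                   n_bins: int = 60,
                   sampling_rate: float | None = None) -> LorentzianFit:
    """Fit the thermal Lorentzian to a PSD and derive the stiffness.

    Least squares on log-power over log-spaced bins in ``[f_lo, f_hi]``
    (defaults: ``fc_guess/10`` to ``min(10*fc_guess, 0.8*Nyquist)``).
    Returns fc, gamma with covariance-propagated standard errors and
    ``k = 2*pi*fc*gamma``.

    With ``sampling_rate`` the fit model is the exact spectrum of the
    *sampled* process (:func:`sampled_ou_psd`), which removes the
    aliasing bias that the plain Lorentzian incurs when the corner
    frequency is not far below Nyquist (a few percent at ``fs*tau ~ 6``).
    Use it when the PSD comes from a finitely sampled trace; leave unset
    to fit the continuous-model Lorentzian itself.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive for a thermal fit")
    f = psd.frequencies
    p = psd.power
    pos = (f > 0) & (p > 0)
    f, p = f[pos], p[pos]
    if f.size < 10:
        raise FitError("fewer than 10 positive-frequency bins available")
    nyquist = psd.frequencies[-1]
    fc_guess = _guess_fc(f, p)
    if f_lo is None:
        f_lo = fc_guess / 10.0
    if f_hi is None:
        f_hi = min(10.0 * fc_guess, 0.8 * nyquist)
    in_range = (f >= f_lo) & (f <= f_hi)
    if np.count_nonzero(in_range) < 10:
        raise FitError(f"fewer than 10 bins in fit range [{f_lo:.3g}, {f_hi:.3g}] Hz")
    fb, pb = _log_bin(f[in_range], p[in_range], n_bins)

    kbt = BOLTZMANN * temperature

    def log_model(freq, log_fc, log_gamma):
        fc = np.exp(log_fc)
        gamma = np.exp(log_gamma)
        if sampling_rate is not None:
            return np.log(sampled_ou_psd(freq, fc, gamma, temperature,
                                         sampling_rate))
        return np.log(kbt / (np.pi**2 * gamma * (fc**2 + freq**2)))

    gamma_guess = kbt / (np.pi**2 * np.median(pb[:3]) * fc_guess**2)
    try:
        popt, pcov = optimize.curve_fit(
            log_model, fb, np.log(pb),
            p0=[np.log(fc_guess), np.log(max(gamma_guess, 1e-300))],
            maxfev=10_000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"Lorentzian fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(popt)) or not np.all(np.isfinite(pcov)):
        raise FitError("Lorentzian fit produced non-finite parameters/covariance")

    log_fc, log_gamma = popt
    fc = float(np.exp(log_fc))
    gamma = float(np.exp(log_gamma))
    var_lfc, var_lg = pcov[0, 0], pcov[1, 1]
    cov_fg = pcov[0, 1]
    fc_se = fc * np.sqrt(max(var_lfc, 0.0))
    gamma_se = gamma * np.sqrt(max(var_lg, 0.0))
    k = 2.0 * np.pi * fc * gamma
    k_se = k * np.sqrt(max(var_lfc + var_lg + 2.0 * cov_fg, 0.0))
    resid = np.log(pb) - log_model(fb, *popt)
    goodness = float(np.sum(resid**2) / max(len(fb) - 2, 1))
    at_boundary = not (1.05 * f_lo < fc < f_hi / 1.05)
    if at_boundary:
        warnings.warn("fitted corner frequency lies at the fit-range boundary",
                      stacklevel=2)
    return LorentzianFit(fc=fc, gamma=gamma, fc_se=float(fc_se),
                         gamma_se=float(gamma_se), stiffness_se=float(k_se),
                         fit_range=(float(f_lo), float(f_hi)),
                         goodness=goodness, at_boundary=at_boundary)


def stiffness_distribution(traces, temperature: float,
                           segment_length: int | None = None,
                           window: str = "hann",
                           f_lo: float | None = None,
                           f_hi: float | None = None,
                           correct_aliasing: bool = False) -> StiffnessDistribution:
    """Calibrate each trace and aggregate the stiffness estimates.

    Per-trace fit failures are excluded and logged in ``failures``; if every
    fit fails a :class:`FitError` is raised.  ``correct_aliasing`` fits the
    exact sampled-process spectrum at each trace's own sampling rate.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    values, failures = [], []
    last_se = None
    for i, tr in enumerate(traces):
        try:
            fit = fit_lorentzian(estimate_psd(tr, segment_length, window),
                                 temperature, f_lo, f_hi,
                                 sampling_rate=tr.fs if correct_aliasing else None)
            values.append(fit.stiffness)
            last_se = fit.stiffness_se
        except (FitError, ValueError) as exc:
            failures.append((i, str(exc)))
    if not values:
        raise FitError(f"all {len(traces)} calibration fits failed: {failures}")
    return StiffnessDistribution.from_values(values, single_fit_se=last_se,
                                             failures=failures)
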