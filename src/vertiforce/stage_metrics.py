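"""Metrology estimators for positioner performance.

Three quantities characterise a scanning-probe positioning stage at the
nanometre scale: the stick-slip step-size statistics, the slow mechanical
drift velocity, and the linear cross-talk between orthogonal scan axes.
Each estimator here consumes the synthetic traces produced by the
simulation modules (or real CSV records) and reports field-standard units
(nm, nm/min, %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cantilever_sim import RasterScan
from .trace import PositionTrace


@dataclass
class StepStats:
    """Signed step sizes with mean, SEM and SD."""

    step_sizes: np.ndarray
    mean: float
    sem: float
    sd: float
    n: int
    direction: str
    indices: np.ndarray

    @classmethod
    def from_sizes(cls, sizes: np.ndarray, indices: np.ndarray) -> "StepStats":
        sizes = np.asarray(sizes, dtype=float)
        n = sizes.size
        if n == 0:
            return cls(step_sizes=sizes, mean=0.0, sem=0.0, sd=0.0, n=0,
                       direction="mixed", indices=np.asarray(indices, dtype=int))
        sd = float(np.std(sizes, ddof=1)) if n > 1 else 0.0
        if np.all(sizes > 0):
            direction = "up"
        elif np.all(sizes < 0):
            direction = "down"
        else:
            direction = "mixed"
        return cls(step_sizes=sizes, mean=float(sizes.mean()),
                   sem=sd / np.sqrt(n) if n > 0 else 0.0, sd=sd, n=n,
                   direction=direction, indices=np.asarray(indices, dtype=int))


@dataclass
class DriftEstimate:
    """Linear drift velocity (SI m/s) with autocorrelation-aware SE."""

    velocity: float
    se: float
    axis: str
    window: float

    @property
    def nm_per_min(self) -> float:
        return self.velocity * 1e9 * 60.0

    @property
    def se_nm_per_min(self) -> float:
        return self.se * 1e9 * 60.0


@dataclass
class CrosstalkResult:
    """Linear coupling between scan axes and residual after correction."""

    c_yx: float
    c_xy: float
    residual_pct: float
    fit_se: float

    def __post_init__(self) -> None:
        if self.residual_pct < 0:
            raise ValueError("residual_pct must be non-negative")


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the median absolute successive difference."""
    d = np.abs(np.diff(x))
    return float(np.median(d) / (np.sqrt(2.0) * 0.6744897501960817))


def detect_steps(trace: PositionTrace, window: int, threshold_sigma: float = 5.0,
                 min_dwell: int | None = None) -> StepStats:
    """Detect discrete steps with a sliding two-window mean-difference test.

    The statistic ``mean(x[i:i+w]) - mean(x[i-w:i])`` is compared against
    ``threshold_sigma`` times its noise-driven SD (noise estimated robustly
    from successive differences); a step is declared at each local extremum
    of the exceeding statistic, detections closer than ``min_dwell`` are
    merged (larger magnitude wins), and the step size is the difference of
    the plateau means on either side.  Offset- and translation-invariant by
    construction.
    """
    x = trace.samples
    n = x.size
    w = int(window)
    if w < 1 or n < 2 * w:
        raise ValueError("trace must be at least twice the window length")
    if min_dwell is None:
        min_dwell = w
    cs = np.concatenate([[0.0], np.cumsum(x)])
    right = (cs[2 * w:] - cs[w:-w]) / w          # mean over [i, i+w)
    left = (cs[w:-w] - cs[:-2 * w]) / w          # mean over [i-w, i)
    stat = right - left                          # indexed by i-w, i in [w, n-w]
    noise = _robust_noise_sd(x)
    thr = threshold_sigma * noise * np.sqrt(2.0 / w)
    if thr == 0.0:
        # noiseless trace: any statistic clear of float error is a step
        thr = 1e-9 * float(np.max(np.abs(stat), initial=0.0))

    above = np.abs(stat) > thr
    # local extrema of |stat| within each above-threshold run
    candidates = []
    j = 0
    m = stat.size
    while j < m:
        if above[j]:
            k = j
            while k < m and above[k]:
                k += 1
            run = np.abs(stat[j:k])
            candidates.append(j + int(np.argmax(run)))
            j = k
        else:
            j += 1
    # merge candidates closer than min_dwell, keeping the larger |stat|
    merged: list[int] = []
    for c in candidates:
        if merged and c - merged[-1] < min_dwell:
            if abs(stat[c]) > abs(stat[merged[-1]]):
                merged[-1] = c
        else:
            merged.append(c)
    idx = np.array(merged, dtype=int) + w        # step positions in sample index

    sizes = []
    for s, i in enumerate(idx):
        lo = idx[s - 1] if s > 0 else 0
        hi = idx[s + 1] if s + 1 < idx.size else n
        lw = min(w, i - lo)
        rw = min(w, hi - i)
        sizes.append(x[i:i + rw].mean() - x[i - lw:i].mean())
    return StepStats.from_sizes(np.array(sizes), idx)


def estimate_drift(trace: PositionTrace) -> DriftEstimate:
    """Drift velocity as the OLS slope of position versus time.

    The standard error is inflated for correlated noise using an effective
    sample size ``n / ceil(tau_est * fs)`` with the noise correlation time
    estimated from the lag-1 autocorrelation of the residuals.
    """
    n = trace.n
    if n < 2:
        raise ValueError("need at least 2 samples")
    if trace.duration < 60.0:
        warnings.warn("trace shorter than 60 s: drift estimate may be unstable",
                      stacklevel=2)
    t = trace.times()
    x = trace.samples
    tc = t - t.mean()
    sxx = float(np.sum(tc**2))
    slope = float(np.sum(tc * x) / sxx)
    resid = x - x.mean() - slope * tc
    rvar = float(np.sum(resid**2) / max(n - 2, 1))
    se = np.sqrt(rvar / sxx)
    # effective-n correction for autocorrelated residuals
    if n > 2 and rvar > 0:
        r1 = float(np.sum(resid[:-1] * resid[1:]) / np.sum(resid**2))
        if 0 < r1 < 1:
            tau_samples = -1.0 / np.log(r1)
            n_eff = n / max(1.0, np.ceil(tau_samples))
            se *= np.sqrt(n / max(n_eff, 2.0))
    return DriftEstimate(velocity=slope, se=float(se), axis=trace.axis_label,
                         window=trace.duration)


def _pooled_line_slope(fast: np.ndarray, slow: np.ndarray,
                       line_index: np.ndarray) -> tuple[float, float, int]:
    """Per-line OLS slope of slow on fast, pooled across lines."""
    slopes = []
    for j in np.unique(line_index):
        m = line_index == j
        xf = fast[m]
        if xf.size < 3 or np.ptp(xf) == 0:
            continue  # degenerate line: no fast-axis range
        xc = xf - xf.mean()
        slopes.append(float(np.sum(xc * slow[m]) / np.sum(xc**2)))
    if not slopes:
        raise ValueError("all scan lines are degenerate (zero fast-axis range)")
    slopes = np.asarray(slopes)
    se = float(np.std(slopes, ddof=1) / np.sqrt(slopes.size)) if slopes.size > 1 else 0.0
    return float(slopes.mean()), se, slopes.size


def estimate_crosstalk(scan: RasterScan) -> CrosstalkResult:
    """Estimate the fast-to-slow axis coupling and the post-correction residual.

    Within each raster line the slow-axis command is constant, so any
    fast-axis-correlated slow-axis motion is cross-talk; the per-line
    regression slopes are pooled into ``c_yx`` (x fast, y slow).  The linear
    correction ``y' = y - c_yx * x`` is then applied and the coupling
    re-estimated; ``residual_pct = 100 * |c_residual|``.  The reverse
    coefficient ``c_xy`` is not identifiable from a single raster (the
    slow-axis command has no within-line variation) and is reported as 0;
    estimate it from a transposed scan.
    """
    if scan.n_lines < 2:
        raise ValueError("need at least 2 scan lines")
    c_yx, se, _ = _pooled_line_slope(scan.meas_x, scan.meas_y, scan.line_index)
    corrected = scan.meas_y - c_yx * scan.meas_x
    c_res, _, _ = _pooled_line_slope(scan.meas_x, corrected, scan.line_index)
    return CrosstalkResult(c_yx=c_yx, c_xy=0.0,
                           residual_pct=100.0 * abs(c_res), fit_se=se)


def apply_crosstalk_correction(scan: RasterScan, c_yx: float) -> RasterScan:
    """Return a scan with the linear slow-axis correction applied."""
    return RasterScan(cmd_x=scan.cmd_x, cmd_y=scan.cmd_y,
                      meas_x=scan.meas_x,
                      meas_y=scan.meas_y - c_yx * scan.meas_x,
                      line_index=scan.line_index,
                      samples_per_line=scan.samples_per_line)
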