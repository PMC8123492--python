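"""Uniformly sampled position time series.

All positions are SI metres internally; nanometres appear only at file and
report boundaries.  The optional per-sample modulation state uses compact
int8 codes (:data:`MOD_OFF`, :data:`MOD_ON`, :data:`MOD_TRANSITION`) so that
multi-minute traces at 48 kHz stay cheap to hold in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MOD_OFF = np.int8(0)
MOD_ON = np.int8(1)
MOD_TRANSITION = np.int8(2)

#: int8 code -> CSV label
MOD_LABELS = {int(MOD_OFF): "off", int(MOD_ON): "on", int(MOD_TRANSITION): "transition"}
#: CSV label -> int8 code
MOD_CODES = {v: np.int8(k) for k, v in MOD_LABELS.items()}

_AXES = ("x", "y", "z", "sum")


@dataclass
class PositionTrace:
    """A uniformly sampled tip/stage position (or sum-signal) time series.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz; must be positive.
    samples : numpy.ndarray
        Positions in metres (or arbitrary units for sum signals); non-empty.
    mod_state : numpy.ndarray, optional
        Per-sample modulation state codes, same length as ``samples``.
    axis_label : str
        One of ``{'x', 'y', 'z', 'sum'}``.
    t0 : float
        Time of the first sample, seconds.
    """

    fs: float
    samples: np.ndarray
    mod_state: np.ndarray | None = None
    axis_label: str = "x"
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.mod_state is not None:
            self.mod_state = np.asarray(self.mod_state, dtype=np.int8)
            if self.mod_state.shape != self.samples.shape:
                raise ValueError("mod_state must match samples in length")
        if self.axis_label not in _AXES:
            raise ValueError(f"axis_label must be one of {_AXES}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n / fs)."""
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (computed, not stored)."""
        return self.t0 + np.arange(self.n) / self.fs

    def decimated(self, factor: int) -> "PositionTrace":
        """Keep every ``factor``-th sample (first sample retained)."""
        factor = int(factor)
        if factor < 1:
            raise ValueError("decimation factor must be >= 1")
        return PositionTrace(
            fs=self.fs / factor,
            samples=self.samples[::factor].copy(),
            mod_state=None if self.mod_state is None else self.mod_state[::factor].copy(),
            axis_label=self.axis_label,
            t0=self.t0,
            meta=dict(self.meta),
        )
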