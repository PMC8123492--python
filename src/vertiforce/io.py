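"""File readers/writers and run configuration.

Traces travel as CSV with header ``t_s,x_nm[,mod]`` (positions in
nanometres, 12 significant digits) or as HDF5 containers that round-trip
bit-exactly.  Run configurations are flat ``key = value`` text files.
"""

from __future__ import annotations

import ast
import os
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .trace import MOD_CODES, MOD_LABELS, PositionTrace


class FormatError(ValueError):
    """Raised for malformed trace or config files."""


_CSV_FS_TOLERANCE = 1e-6  # relative sampling-interval jitter tolerated (1 ppm)


def write_trace(trace: PositionTrace, path: str | os.PathLike) -> None:
    """Write a trace; format chosen by extension (.h5/.hdf5 binary, else CSV)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_h5(trace, path)
    else:
        _write_csv(trace, path)


def read_trace(path: str | os.PathLike) -> PositionTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_h5(path)
    return _read_csv(path)


def _write_csv(trace: PositionTrace, path: Path) -> None:
    cols = {"t_s": trace.times(), "x_nm": trace.samples * 1e9}
    if trace.mod_state is not None:
        cols["mod"] = [MOD_LABELS[int(c)] for c in trace.mod_state]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def _read_csv(path: Path) -> PositionTrace:
    df = pd.read_csv(path)
    required = {"t_s", "x_nm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing required columns {required - set(df.columns)}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    mean_dt = dt.mean()
    if mean_dt <= 0 or np.max(np.abs(dt - mean_dt)) > _CSV_FS_TOLERANCE * mean_dt:
        raise FormatError(f"{path}: non-uniform sampling (> 1 ppm jitter)")
    mod = None
    if "mod" in df.columns:
        labels = df["mod"].astype(str).tolist()
        bad = [i for i, s in enumerate(labels) if s not in MOD_CODES]
        if bad:
            raise FormatError(
                f"{path}: invalid mod value {labels[bad[0]]!r} at row {bad[0]}"
            )
        mod = np.array([MOD_CODES[s] for s in labels], dtype=np.int8)
    return PositionTrace(fs=1.0 / mean_dt, samples=df["x_nm"].to_numpy(dtype=float) * 1e-9,
                         mod_state=mod, t0=float(t[0]))


def _write_h5(trace: PositionTrace, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("samples", data=trace.samples)
        if trace.mod_state is not None:
            h5.create_dataset("mod_state", data=trace.mod_state)
        h5.attrs["fs"] = trace.fs
        h5.attrs["axis_label"] = trace.axis_label
        h5.attrs["t0"] = trace.t0
        for key, value in trace.meta.items():
            h5.attrs[f"meta_{key}"] = value


def _read_h5(path: Path) -> PositionTrace:
    with h5py.File(path, "r") as h5:
        if "samples" not in h5:
            raise FormatError(f"{path}: missing 'samples' dataset")
        samples = h5["samples"][:]
        mod = h5["mod_state"][:] if "mod_state" in h5 else None
        meta = {k[5:]: (v.item() if hasattr(v, "item") else v)
                for k, v in h5.attrs.items() if k.startswith("meta_")}
        return PositionTrace(fs=float(h5.attrs["fs"]), samples=samples,
                             mod_state=mod, axis_label=str(h5.attrs["axis_label"]),
                             t0=float(h5.attrs["t0"]), meta=meta)


def write_raster_csv(scan, path: str | os.PathLike) -> None:
    """Raster scans as CSV ``cmd_x_nm,cmd_y_nm,meas_x_nm,meas_y_nm,line``."""
    pd.DataFrame({
        "cmd_x_nm": scan.cmd_x * 1e9, "cmd_y_nm": scan.cmd_y * 1e9,
        "meas_x_nm": scan.meas_x * 1e9, "meas_y_nm": scan.meas_y * 1e9,
        "line": scan.line_index,
    }).to_csv(path, index=False, float_format="%.12g")


def read_raster_csv(path: str | os.PathLike):
    from .cantilever_sim import RasterScan

    df = pd.read_csv(path)
    required = {"cmd_x_nm", "cmd_y_nm", "meas_x_nm", "meas_y_nm", "line"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    line = df["line"].to_numpy(dtype=int)
    spl = int(np.bincount(line).max())
    return RasterScan(
        cmd_x=df["cmd_x_nm"].to_numpy(float) * 1e-9,
        cmd_y=df["cmd_y_nm"].to_numpy(float) * 1e-9,
        meas_x=df["meas_x_nm"].to_numpy(float) * 1e-9,
        meas_y=df["meas_y_nm"].to_numpy(float) * 1e-9,
        line_index=line, samples_per_line=spl,
    )


@dataclass
class RunConfig:
    """Flat key-value run configuration with a seed and output directory.

    Unknown keys (not in ``defaults``) are rejected at load time; every
    parameter therefore has a documented default.  Round-trips exactly
    through :meth:`write` / :meth:`read`.
    """

    scenario: str
    seed: int = 0
    out_dir: str = "."
    params: dict = field(default_factory=dict)

    def write(self, path: str | os.PathLike) -> None:
        lines = [f"scenario = {self.scenario}", f"seed = {self.seed}",
                 f"out_dir = {self.out_dir}"]
        for key in sorted(self.params):
            lines.append(f"{key} = {self.params[key]!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | os.PathLike, defaults: dict | None = None) -> "RunConfig":
        scenario, seed, out_dir, params = "", 0, ".", {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "scenario":
                scenario = value
            elif key == "seed":
                seed = int(value)
            elif key == "out_dir":
                out_dir = value
            else:
                if defaults is not None and key not in defaults:
                    raise FormatError(f"{path}:{ln}: unknown parameter {key!r}")
                try:
                    params[key] = ast.literal_eval(value)
                except (ValueError, SyntaxError) as exc:
                    raise FormatError(f"{path}:{ln}: bad value {value!r}") from exc
        if not scenario:
            raise FormatError(f"{path}: missing 'scenario'")
        return cls(scenario=scenario, seed=seed, out_dir=out_dir, params=params)
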