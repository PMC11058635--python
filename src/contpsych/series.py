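"""Uniformly sampled direction-angle time series and their text I/O.

Angles are in degrees, measured clockwise from vertical (vertical = 0,
positive = clockwise / rightward).  Series are stored unwrapped: values may
transiently exceed +/-90 if the generating process permits it.

Files are plain delimited text with a ``time`` column in seconds followed by
one or more named angle columns, e.g. ``time,x`` or ``time,x,y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataFormatError

#: absolute tolerance (seconds) when validating a uniform time grid
GRID_ATOL = 1e-6


@dataclass
class AngleSeries:
    """A uniformly sampled time series of direction angles.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds (> 0).
    values : array-like
        Angles in degrees, clockwise from vertical.
    t0 : float
        Time of the first sample, seconds.
    meta : dict
        Free-form provenance (seed, generating config, clip counts ...).
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ConfigError(f"sampling interval dt must be positive, got {self.dt}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigError("series values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("series contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def with_values(self, values: np.ndarray, **meta) -> "AngleSeries":
        """Copy of this series with new values on the same grid."""
        out = replace(self, values=np.asarray(values, dtype=float))
        out.meta = {**self.meta, **meta}
        return out

    def discard_initial(self, seconds: float) -> "AngleSeries":
        """Drop the leading ``seconds`` of data (warm-up / unanalyzed segment)."""
        if seconds <= 0:
            return self
        k = int(round(seconds / self.dt))
        if k >= self.n:
            raise ConfigError(
                f"discard of {seconds} s leaves no data (series spans {self.duration} s)"
            )
        return AngleSeries(
            dt=self.dt, values=self.values[k:], t0=self.t0 + k * self.dt, meta=dict(self.meta)
        )

    def same_grid(self, other: "AngleSeries") -> bool:
        return (
            self.n == other.n
            and abs(self.dt - other.dt) < GRID_ATOL
            and abs(self.t0 - other.t0) < GRID_ATOL
        )


def _validate_grid(time: np.ndarray, path: str) -> float:
    if time.size < 2:
        raise DataFormatError(f"{path}: need at least two rows to define a grid")
    steps = np.diff(time)
    dt = steps[0]
    bad = np.nonzero(np.abs(steps - dt) > GRID_ATOL)[0]
    if bad.size:
        row = int(bad[0]) + 2  # +1 for 0-based diff, +1 for header line
        raise DataFormatError(
            f"{path}: non-uniform time grid at data row {row} "
            f"(step {steps[bad[0]]:.6g} s, expected {dt:.6g} s)"
        )
    return float(dt)


def read_frame(path) -> tuple[pd.DataFrame, float]:
    """Read a delimited series file, validate its grid, return (frame, dt)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataFormatError(f"{path}: {exc}") from exc
    if df.columns[0] != "time":
        raise DataFormatError(f"{path}: first column must be 'time', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected at least one angle column after 'time'")
    dt = _validate_grid(df["time"].to_numpy(dtype=float), str(path))
    return df, dt


def read_series(path, column: str | None = None) -> AngleSeries:
    """Read a single-channel series (``time,<name>``) from delimited text."""
    df, dt = read_frame(path)
    name = column if column is not None else df.columns[1]
    if name not in df.columns:
        raise DataFormatError(f"{path}: no column named {name!r}")
    return AngleSeries(
        dt=dt,
        values=df[name].to_numpy(dtype=float),
        t0=float(df["time"].iloc[0]),
        meta={"source": str(path), "column": name},
    )


def write_series(series: AngleSeries, path, name: str = "x") -> None:
    """Write a single series as ``time,<name>`` delimited text."""
    pd.DataFrame({"time": series.times, name: series.values}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_pair(path, names: tuple[str, str] = ("x", "y")) -> tuple[AngleSeries, AngleSeries]:
    """Read an aligned (independent, dependent) pair from ``time,x,y`` text."""
    df, dt = read_frame(path)
    out = []
    for name in names:
        if name not in df.columns:
            raise DataFormatError(f"{path}: no column named {name!r}")
        out.append(
            AngleSeries(
                dt=dt,
                values=df[name].to_numpy(dtype=float),
                t0=float(df["time"].iloc[0]),
                meta={"source": str(path), "column": name},
            )
        )
    return out[0], out[1]


def write_columns(path, time: np.ndarray, **columns) -> None:
    """Write several aligned columns (``time`` first) as delimited text."""
    pd.DataFrame({"time": time, **columns}).to_csv(path, index=False, float_format="%.10g")
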