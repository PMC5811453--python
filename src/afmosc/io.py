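"""Time-series input/output and resampling.

AFM acquisition software exports real-time adhesion-force and E-modulus
records as two-column delimited text (time in seconds, value in pN or kPa).
Acquisition gaps make many of these series unevenly sampled; the singular
spectrum analysis stage requires a uniform grid, so uneven series are
linearly interpolated onto one before analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, ParseError

__all__ = [
    "Quantity",
    "TimeSeries",
    "read_timeseries",
    "write_timeseries",
    "resample_uniform",
    "write_bundle",
    "read_bundle",
]

#: Tolerance on successive time deltas when deciding a series is uniform.
UNIFORM_TOL = 1e-6


class Quantity(str, enum.Enum):
    """Physical quantity carried by a time series."""

    ADHESION_FORCE = "adhesion_force"  # pN
    E_MODULUS = "e_modulus"  # kPa

    @property
    def unit(self) -> str:
        return {"adhesion_force": "pN", "e_modulus": "kPa"}[self.value]


@dataclass(frozen=True)
class TimeSeries:
    """A timestamped physical quantity x_1 ... x_N.

    Parameters
    ----------
    times
        Sample times in seconds, non-negative and strictly increasing.
    values
        Sample values (pN for adhesion force, kPa for E-modulus).
    quantity
        Which physical quantity the values represent.
    sampling_rate
        Sampling rate in Hz; set iff the series is uniformly sampled.
    """

    times: np.ndarray
    values: np.ndarray
    quantity: Quantity
    sampling_rate: float | None = field(default=None)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise InputError("times and values must be 1-D arrays of equal length")
        if len(times) < 2:
            raise InputError("a time series needs at least 2 samples")
        if times[0] < 0:
            raise InputError("times must be non-negative")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise InputError("times must be strictly increasing (no duplicates)")
        if self.sampling_rate is not None:
            if self.sampling_rate <= 0:
                raise ParameterError("sampling_rate must be positive")
            if np.max(np.abs(dt - 1.0 / self.sampling_rate)) >= UNIFORM_TOL:
                raise InputError(
                    "sampling_rate set but time grid is not uniform at that rate"
                )

    @property
    def N(self) -> int:
        """Number of samples."""
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def is_uniform(self, tol: float = UNIFORM_TOL) -> bool:
        dt = np.diff(self.times)
        return bool(np.max(np.abs(dt - dt.mean())) < tol)


def _looks_numeric(tokens: list[str]) -> bool:
    try:
        [float(t) for t in tokens]
    except ValueError:
        return False
    return True


def read_timeseries(
    path,
    quantity: Quantity | str,
    *,
    delimiter: str | None = None,
) -> TimeSeries:
    """Read a two-column (time, value) delimited text file.

    The delimiter is auto-detected among comma / tab / whitespace unless
    given, and a single header line is auto-detected and skipped.  Rows are
    sorted by time; duplicate timestamps are an error.
    """
    quantity = Quantity(quantity)
    sep = delimiter if delimiter is not None else None
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            engine="python",
            header=None,
            comment="#",
            skip_blank_lines=True,
            dtype=str,
        )
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: cannot parse: {exc}") from exc

    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    df = df.iloc[:, :2]

    start = 0
    first = [str(v).strip() for v in df.iloc[0]]
    if not _looks_numeric(first):
        start = 1  # header line
    if len(df) - start < 2:
        raise InputError(f"{path}: fewer than 2 data rows")

    body = df.iloc[start:]
    numeric = body.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # pandas index counts from 0 over parsed rows; +1 for 1-based lines
        line = int(bad.idxmax()) + 1
        raise ParseError(f"{path}: non-numeric cell on line {line}")

    times = numeric.iloc[:, 0].to_numpy(float)
    values = numeric.iloc[:, 1].to_numpy(float)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    if np.any(np.diff(times) == 0):
        raise InputError(f"{path}: duplicate timestamps")

    rate = None
    dt = np.diff(times)
    if np.max(np.abs(dt - dt.mean())) < UNIFORM_TOL:
        rate = 1.0 / dt.mean()
    return TimeSeries(times, values, quantity, sampling_rate=rate)


def write_timeseries(path, ts: TimeSeries, *, delimiter: str = ",") -> None:
    """Write a time series as two-column delimited text with a header."""
    header = f"time_s{delimiter}{ts.quantity.value}_{ts.quantity.unit}"
    np.savetxt(
        path,
        np.column_stack([ts.times, ts.values]),
        delimiter=delimiter,
        header=header,
        comments="",
        fmt="%.10g",
    )


def resample_uniform(ts: TimeSeries, target_rate: float = 0.5) -> TimeSeries:
    """Resample onto a uniform grid by piecewise-linear interpolation.

    The grid starts at ``ts.times[0]`` with spacing ``1/target_rate`` and
    never extends beyond ``ts.times[-1]`` (no extrapolation).  The default
    rate of 0.5 Hz matches the AFM acquisition cycle rate.
    """
    if target_rate <= 0:
        raise ParameterError("target_rate must be positive")
    dt = 1.0 / target_rate
    n = int(np.floor(ts.duration / dt + 1e-9)) + 1
    if n < 2:
        raise InputError("target grid would have fewer than 2 samples")
    grid = ts.times[0] + dt * np.arange(n)
    values = np.interp(grid, ts.times, ts.values)
    return TimeSeries(grid, values, ts.quantity, sampling_rate=target_rate)


def write_bundle(path, cell_id: str, datasets: dict[str, np.ndarray], *, attrs: dict | None = None) -> None:
    """Append pipeline intermediates for one cell to an HDF5 container.

    One group per cell; datasets are typically ``raw``, ``standardized``,
    ``components`` and ``spectra`` arrays.
    """
    with h5py.File(path, "a") as h5:
        if cell_id in h5:
            del h5[cell_id]
        grp = h5.create_group(cell_id)
        for name, arr in datasets.items():
            grp.create_dataset(name, data=np.asarray(arr))
        for key, val in (attrs or {}).items():
            grp.attrs[key] = val


def read_bundle(path, cell_id: str) -> dict[str, np.ndarray]:
    """Read one cell's datasets back from an HDF5 container."""
    with h5py.File(path, "r") as h5:
        if cell_id not in h5:
            raise InputError(f"{path}: no group {cell_id!r}")
        return {name: ds[()] for name, ds in h5[cell_id].items()}
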