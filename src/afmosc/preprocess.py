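"""Linear detrending and standardization ahead of singular spectrum analysis.

Slow instrumental drift (thermal and mechanical) appears as a near-linear
trend in real-time AFM records.  The trend is removed by ordinary
least-squares, and the residual is standardized to zero mean and unit
sample standard deviation so that eigenvalue fractions are comparable
across cells.  The fitted trend is retained so reconstructed components
can be reported back on the physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSeriesError, InputError
from .io import Quantity, TimeSeries

__all__ = [
    "TrendModel",
    "StandardizedSeries",
    "fit_linear_trend",
    "detrend_standardize",
    "restore_scale",
]


@dataclass(frozen=True)
class TrendModel:
    """Linear trend plus residual moments, sufficient to invert standardization.

    ``mean`` and ``std`` are the mean and sample standard deviation of the
    detrended residuals (``mean`` is ~0 for an OLS fit with intercept, but is
    stored so the inverse transform is exact).
    """

    slope: float  # quantity units per second
    intercept: float  # quantity units
    mean: float  # quantity units
    std: float  # quantity units
    slope_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise DegenerateSeriesError("residual standard deviation must be > 0")

    def predict(self, times: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(times, float) + self.intercept


@dataclass(frozen=True)
class StandardizedSeries:
    """Dimensionless series with zero mean and unit sample std."""

    times: np.ndarray
    values: np.ndarray
    sampling_rate: float
    trend: TrendModel
    source_quantity: Quantity

    @property
    def N(self) -> int:
        return len(self.values)


def fit_linear_trend(ts: TimeSeries) -> TrendModel:
    """Ordinary least-squares line through (time, value).

    Raises
    ------
    DegenerateSeriesError
        If the residuals have zero variance (an exact line), in which case
        standardization is undefined.
    """
    if ts.sampling_rate is None:
        raise InputError("series must be uniformly sampled; resample first")
    if ts.N < 3:
        raise InputError("need at least 3 samples to fit and standardize")
    res = stats.linregress(ts.times, ts.values)
    residual = ts.values - (res.slope * ts.times + res.intercept)
    std = float(np.std(residual, ddof=1))
    if std <= 0 or not np.isfinite(std):
        raise DegenerateSeriesError("series is an exact line; residual variance is 0")
    return TrendModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        mean=float(residual.mean()),
        std=std,
        slope_stderr=float(res.stderr),
    )


def detrend_standardize(ts: TimeSeries) -> StandardizedSeries:
    """Subtract the OLS line, then center and scale the residuals.

    Output has mean 0 and sample standard deviation 1 by construction.
    """
    trend = fit_linear_trend(ts)
    residual = ts.values - trend.predict(ts.times)
    values = (residual - trend.mean) / trend.std
    return StandardizedSeries(
        times=ts.times.copy(),
        values=values,
        sampling_rate=float(ts.sampling_rate),
        trend=trend,
        source_quantity=ts.quantity,
    )


def restore_scale(s: StandardizedSeries, include_trend: bool = False) -> TimeSeries:
    """Map a standardized (or component) series back to physical units.

    ``x = s·std + mean``, plus ``slope·t + intercept`` when ``include_trend``
    is set.  Used to report reconstructed oscillatory components in pN / kPa.
    """
    values = s.values * s.trend.std + s.trend.mean
    if include_trend:
        values = values + s.trend.predict(s.times)
    return TimeSeries(
        s.times.copy(), values, s.source_quantity, sampling_rate=s.sampling_rate
    )
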