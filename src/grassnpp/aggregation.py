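"""Temporal aggregation: annual/seasonal NPP, anomalies, trends, ACF.

Annual NPP is the January-December sum with December-February forced to
zero (growing-season NPP); meteorological seasons are used, so under the
winter-zero rule the annual total is exactly spring + summer + autumn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf

from .casa_core import NppSeries, WINTER_MONTHS
from .errors import ConfigError, DataValidationError
from .raster_io import MonthlyStack

__all__ = [
    "SEASONS",
    "AnnualSeries",
    "annual_npp",
    "seasonal_npp",
    "seasonal_sum",
    "seasonal_mean",
    "regional_mean_series",
    "linear_trend",
    "acf",
    "livestock_to_standard_sheep",
]

# Meteorological seasons; winter exists only to state the partition of 1..12.
SEASONS: dict[str, tuple[int, ...]] = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


@dataclass
class AnnualSeries:
    """Regional yearly series with anomalies about the period mean."""

    years: list[int]
    values: np.ndarray
    variable: str = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != self.values.size:
            raise ConfigError("years and values lengths differ")

    @property
    def anomalies(self) -> np.ndarray:
        return self.values - np.nanmean(self.values)


def _winterized(monthly: MonthlyStack | NppSeries) -> MonthlyStack:
    stack = monthly.monthly if isinstance(monthly, NppSeries) else monthly
    data = stack.data.copy()
    idx = [m - 1 for m in WINTER_MONTHS]
    data[:, idx] = np.where(np.isnan(data[:, idx]), np.nan, 0.0)
    return stack.copy_like(data)


def annual_npp(monthly: MonthlyStack | NppSeries) -> np.ndarray:
    """Per-pixel annual (growing-season) NPP, shape (n_years, rows, cols).

    Sum over the 12 months with Dec/Jan/Feb forced to zero, so January
    production never contributes. Accumulated season by season, so the
    annual total equals the spring+summer+autumn sum bit-exactly.
    """
    stack = _winterized(monthly)
    return sum(seasonal_sum(stack, s) for s in ("spring", "summer", "autumn", "winter"))


def seasonal_npp(monthly: MonthlyStack | NppSeries, season: str) -> np.ndarray:
    """Per-pixel seasonal NPP sum for spring/summer/autumn."""
    if season not in SEASONS:
        raise ConfigError(f"unknown season {season!r}; choose from {sorted(SEASONS)}")
    if season == "winter":
        raise ConfigError("winter NPP is identically zero and never requested")
    return seasonal_sum(_winterized(monthly), season)


def seasonal_sum(stack: MonthlyStack | NppSeries, season: str) -> np.ndarray:
    """Sum a monthly stack over one season's months, per pixel-year."""
    s = stack.monthly if isinstance(stack, NppSeries) else stack
    months = SEASONS.get(season)
    if not months:
        raise ConfigError(f"unknown or empty season {season!r}")
    return s.data[:, [m - 1 for m in months]].sum(axis=1)


def seasonal_mean(stack: MonthlyStack, season: str) -> np.ndarray:
    """Mean of a monthly stack over one season's months (e.g. temperature)."""
    months = SEASONS.get(season)
    if not months:
        raise ConfigError(f"unknown or empty season {season!r}")
    return stack.data[:, [m - 1 for m in months]].mean(axis=1)


def regional_mean_series(per_year: np.ndarray, years: list[int],
                         mask: np.ndarray | None = None,
                         variable: str = "value") -> AnnualSeries:
    """Spatial mean over valid (non-nodata, optionally masked) pixels per year."""
    per_year = np.asarray(per_year, dtype=float)
    if per_year.shape[0] != len(years):
        raise ConfigError("leading axis must be years")
    vals = per_year.reshape(per_year.shape[0], -1)
    if mask is not None:
        vals = per_year[:, np.asarray(mask, dtype=bool)]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(vals, axis=1)
    return AnnualSeries(years=list(years), values=means, variable=variable)


def linear_trend(series: AnnualSeries) -> dict:
    """OLS of value on year: slope, intercept, r2, two-tailed p for slope."""
    ok = np.isfinite(series.values)
    if ok.sum() < 3:
        raise DataValidationError("trend needs at least 3 finite points")
    res = stats.linregress(np.asarray(series.years, dtype=float)[ok],
                           series.values[ok])
    return {"slope": res.slope, "intercept": res.intercept,
            "r2": res.rvalue ** 2, "p": res.pvalue, "n": int(ok.sum())}


def acf(values: np.ndarray, max_lag: int) -> dict:
    """Sample autocorrelation by lag with the usual +-1.96/sqrt(n) bounds."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if max_lag >= n:
        raise ConfigError(f"max_lag {max_lag} must be < series length {n}")
    rho = _sm_acf(values, nlags=max_lag, fft=False)
    bound = 1.96 / np.sqrt(n)
    return {"lags": list(range(max_lag + 1)), "acf": rho,
            "lower": -bound, "upper": bound, "n": n}


def livestock_to_standard_sheep(cattle_horses, sheep):
    """Standard-sheep units: sheep + 5 x large livestock (cattle or horses)."""
    cattle_horses = np.asarray(cattle_horses, dtype=float)
    sheep = np.asarray(sheep, dtype=float)
    if (cattle_horses < 0).any() or (sheep < 0).any():
        raise DataValidationError("livestock head counts cannot be negative")
    return sheep + 5.0 * cattle_horses
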