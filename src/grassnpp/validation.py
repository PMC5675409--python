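"""Validation of modelled NPP against clip-plot biomass observations.

Observed NPP comes from paired aboveground + belowground dry biomass via
the 0.475 biomass-to-carbon coefficient. Estimated NPP is the modelled
monthly sum from January up to the sampling month at the pixel containing
each plot. The statistic suite is an OLS regression of estimated (y) on
observed (x) with t-tests on both coefficients, the regression F-test,
RMSE = sqrt(mean((P-O)^2)) and bias = mean(O - P) (observed minus
estimated, so a negative bias means the model runs slightly high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .casa_core import NppSeries
from .errors import ConfigError, DataValidationError
from .raster_io import RasterGrid

__all__ = [
    "BIOMASS_TO_CARBON",
    "ValidationTable",
    "biomass_to_npp",
    "extract_estimates",
    "validation_stats",
]

BIOMASS_TO_CARBON = 0.475  # g dry biomass -> gC


@dataclass
class ValidationTable:
    """Paired observed vs estimated NPP (gC m-2) at plot locations."""

    frame: pd.DataFrame  # columns: plot_id, x, y, observed_npp, estimated_npp

    def __post_init__(self) -> None:
        required = {"x", "y", "observed_npp", "estimated_npp"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigError(f"validation table missing columns {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def observed(self) -> np.ndarray:
        return self.frame["observed_npp"].to_numpy(dtype=float)

    @property
    def estimated(self) -> np.ndarray:
        return self.frame["estimated_npp"].to_numpy(dtype=float)


def biomass_to_npp(agb, bgb):
    """(AGB + BGB) * 0.475: total dry biomass (g m-2) to NPP (gC m-2)."""
    agb = np.asarray(agb, dtype=float)
    bgb = np.asarray(bgb, dtype=float)
    if (agb < 0).any() or (bgb < 0).any():
        raise DataValidationError("biomass cannot be negative")
    return (agb + bgb) * BIOMASS_TO_CARBON


def extract_estimates(npp: NppSeries, plots: pd.DataFrame, year: int,
                      through_month: int = 7) -> ValidationTable:
    """Sum modelled NPP over months 1..through_month at each plot's pixel.

    ``plots`` needs columns x, y, agb, bgb (and optionally plot_id).
    Winter months contribute zero by construction, so through_month=7
    covers March-July production, and through_month=12 is annual NPP.
    """
    if not (1 <= through_month <= 12):
        raise ConfigError(f"through_month must be in 1..12, got {through_month}")
    grid: RasterGrid = npp.grid
    if year not in npp.years:
        raise DataValidationError(f"year {year} not in modelled series {npp.years}")
    yi = npp.years.index(year)
    cum = npp.monthly.data[yi, :through_month].sum(axis=0)
    rows = []
    for i, row in plots.reset_index(drop=True).iterrows():
        r, c = grid.index_of(float(row["x"]), float(row["y"]))  # raises outside grid
        rows.append({
            "plot_id": row.get("plot_id", i),
            "x": float(row["x"]), "y": float(row["y"]),
            "observed_npp": float(biomass_to_npp(row["agb"], row["bgb"])),
            "estimated_npp": float(cum[r, c]),
        })
    return ValidationTable(frame=pd.DataFrame(rows))


def validation_stats(table: ValidationTable) -> dict:
    """Goodness-of-fit suite for estimated (P) vs observed (O) NPP.

    Returns slope, intercept, r2, F and p-values from the OLS of P on O,
    plus rmse and bias (mean(O-P)).
    """
    obs = table.observed
    est = table.estimated
    if table.n < 3:
        raise DataValidationError(f"need at least 3 plots, got {table.n}")
    if not (np.isfinite(obs).all() and np.isfinite(est).all()):
        raise DataValidationError("non-finite values in validation table")
    if np.ptp(obs) == 0:
        raise DataValidationError("zero variance in observed NPP")

    res = stats.linregress(obs, est)
    n = table.n
    r2 = res.rvalue ** 2
    # F-test of the regression; identical to t^2 of the slope for one predictor
    if r2 < 1.0:
        f_stat = r2 / (1 - r2) * (n - 2)
        p_f = float(stats.f.sf(f_stat, 1, n - 2))
    else:
        f_stat, p_f = np.inf, 0.0
    # t-test of the intercept against 0
    resid = est - (res.intercept + res.slope * obs)
    dof = n - 2
    s2 = (resid ** 2).sum() / dof if dof > 0 else 0.0
    sxx = ((obs - obs.mean()) ** 2).sum()
    se_int = np.sqrt(s2 * (1.0 / n + obs.mean() ** 2 / sxx))
    t_int = res.intercept / se_int if se_int > 0 else np.inf
    p_int = float(2 * stats.t.sf(abs(t_int), dof)) if np.isfinite(t_int) else 0.0

    return {
        "n": n,
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(r2),
        "p_slope": float(res.pvalue),
        "p_intercept": p_int,
        "f_stat": float(f_stat),
        "p_f": p_f,
        "rmse": float(np.sqrt(np.mean((est - obs) ** 2))),
        "bias": float(np.mean(obs - est)),
    }
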