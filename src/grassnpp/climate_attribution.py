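"""Pixel- and county-scale climate attribution of NPP.

Per pixel over the study years, NPP is correlated with precipitation and
temperature (Pearson R), and first-order partial correlations

    Rp = (r12 - r13 * r23) / sqrt((1 - r13^2) * (1 - r23^2))

remove the influence of the other climate variable. Significance is a
two-tailed t-test with t = r * sqrt((n - k) / (1 - r^2)), k = 2 for plain
and 3 for partial correlations, applied per pixel without multiple-testing
correction (an optional BH/FDR flag is available). County-level tables use
county-mean series first, then the same Pearson machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aggregation import SEASONS
from .errors import ConfigError, DataValidationError

__all__ = [
    "AttributionMap",
    "pearson_r",
    "partial_r",
    "correlation_map",
    "county_table",
    "map_summary",
]


@dataclass
class AttributionMap:
    """Per-pixel correlation (or partial correlation) with significance."""

    r: np.ndarray
    p: np.ndarray
    n_years: int
    kind: str                  # "correlation" | "partial"
    target: str                # "precipitation" | "temperature"
    controlled: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("correlation", "partial"):
            raise ConfigError(f"kind must be correlation|partial, got {self.kind!r}")
        if self.kind == "partial" and not self.controlled:
            raise ConfigError("partial maps must record the controlled variable")


def pearson_r(x, y):
    """Product-moment correlation; NaN where either series is degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("series lengths differ")
    if x.size < 3:
        raise DataValidationError("correlation needs at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd ** 2).sum() * (yd ** 2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def partial_r(r12, r13, r23):
    """First-order partial correlation of 1 and 2 controlling for 3.

    NaN where a control correlation is +-1 (collinear control).
    """
    r12 = np.asarray(r12, dtype=float)
    r13 = np.asarray(r13, dtype=float)
    r23 = np.asarray(r23, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt((1 - r13 ** 2) * (1 - r23 ** 2))
        out = np.where(denom > 0, (r12 - r13 * r23) / denom, np.nan)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _stack_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r along the leading (year) axis, vectorised over pixels."""
    ad = a - a.mean(axis=0)
    bd = b - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt((ad ** 2).sum(axis=0) * (bd ** 2).sum(axis=0))
        r = np.where(denom > 0, (ad * bd).sum(axis=0) / denom, np.nan)
    return np.clip(r, -1.0, 1.0)


def _p_from_r(r: np.ndarray, n: int, k: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - k) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), n - k)
    p = np.where(np.isnan(r), np.nan, np.where(np.isinf(t), 0.0, p))
    return p


def correlation_map(npp: np.ndarray, climate: np.ndarray,
                    control: np.ndarray | None = None,
                    target: str = "precipitation",
                    controlled: str | None = None,
                    fdr: bool = False) -> AttributionMap:
    """Per-pixel (partial) correlation of yearly NPP with a climate stack.

    Inputs are (n_years, rows, cols) stacks on one grid. With ``control``
    the first-order partial correlation is computed from the three pairwise
    coefficients. Pixels with a degenerate series are nodata.
    """
    npp = np.asarray(npp, dtype=float)
    climate = np.asarray(climate, dtype=float)
    if npp.shape != climate.shape:
        raise ConfigError("NPP and climate stacks must share shape")
    n = npp.shape[0]
    if control is None:
        if n < 3:
            raise DataValidationError("correlation needs >= 3 years")
        r = _stack_corr(npp, climate)
        p = _p_from_r(r, n, 2)
        kind = "correlation"
    else:
        control = np.asarray(control, dtype=float)
        if control.shape != npp.shape:
            raise ConfigError("control stack must share shape")
        if n < 4:
            raise DataValidationError("partial correlation needs >= 4 years")
        r12 = _stack_corr(npp, climate)
        r13 = _stack_corr(npp, control)
        r23 = _stack_corr(climate, control)
        r = partial_r(r12, r13, r23)
        r = np.where(np.isclose(np.abs(r13), 1.0) | np.isclose(np.abs(r23), 1.0),
                     np.nan, r)
        p = _p_from_r(r, n, 3)
        kind = "partial"
    if fdr:
        valid = np.isfinite(p)
        if valid.any():
            p = p.copy()
            p[valid] = multipletests(p[valid].ravel(), method="fdr_bh")[1]
    return AttributionMap(r=r, p=p, n_years=n, kind=kind, target=target,
                          controlled=controlled if control is not None else None)


def county_table(npp_monthly: np.ndarray, precip_monthly: np.ndarray,
                 temp_monthly: np.ndarray, counties: np.ndarray,
                 years: list[int],
                 county_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Annual and seasonal NPP-climate correlations per county.

    Stacks are (n_years, 12, rows, cols). County-mean series are formed
    first (NPP and precipitation summed over months, temperature averaged),
    then Pearson r per county for annual, spring, summer and autumn. The
    output mirrors the classic eight-column layout AP, AMT, SpP, SpMT,
    SuP, SuMT, AuP, AuMT with 0.05/0.01 two-tailed significance stars.
    """
    counties = np.asarray(counties)
    n = len(years)
    season_months = {"annual": tuple(range(1, 13)), "spring": SEASONS["spring"],
                     "summer": SEASONS["summer"], "autumn": SEASONS["autumn"]}
    col_prefix = {"annual": ("AP", "AMT"), "spring": ("SpP", "SpMT"),
                  "summer": ("SuP", "SuMT"), "autumn": ("AuP", "AuMT")}
    rows = []
    for cid in sorted(np.unique(counties[counties > 0])):
        mask = counties == cid
        row: dict = {"county": (county_names or {}).get(int(cid), f"county_{int(cid)}")}
        for season, months in season_months.items():
            idx = [m - 1 for m in months]
            npp_series = np.array([
                np.nansum(np.nanmean(npp_monthly[yi][:, mask], axis=1)[idx])
                for yi in range(n)])
            p_series = np.array([
                np.nansum(np.nanmean(precip_monthly[yi][:, mask], axis=1)[idx])
                for yi in range(n)])
            t_series = np.array([
                np.nanmean(np.nanmean(temp_monthly[yi][:, mask], axis=1)[idx])
                for yi in range(n)])
            pcol, tcol = col_prefix[season]
            for col, clim in ((pcol, p_series), (tcol, t_series)):
                r = pearson_r(npp_series, clim) if np.ptp(clim) > 0 and np.ptp(npp_series) > 0 else np.nan
                p = float(_p_from_r(np.array(r), n, 2)) if np.isfinite(r) else np.nan
                row[col] = r
                row[col + "_p"] = p
                row[col + "_sig"] = ("**" if p < 0.01 else "*" if p < 0.05 else "") \
                    if np.isfinite(p) else ""
        rows.append(row)
    return pd.DataFrame(rows)


def map_summary(amap: AttributionMap, alpha: float = 0.05,
                bin_width: float = 0.1) -> dict:
    """Fractions of valid pixels positive/negative/significant + histogram."""
    r = amap.r[np.isfinite(amap.r)]
    p = amap.p[np.isfinite(amap.r)]
    n_valid = r.size
    if n_valid == 0:
        raise DataValidationError("no valid pixels in attribution map")
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(r, bins=edges)
    return {
        "n_valid": int(n_valid),
        "frac_positive": float((r > 0).sum() / n_valid),
        "frac_negative": float((r < 0).sum() / n_valid),
        "frac_significant": float((p < alpha).sum() / n_valid),
        "frac_positive_significant": float(((r > 0) & (p < alpha)).sum() / n_valid),
        "frac_negative_significant": float(((r < 0) & (p < alpha)).sum() / n_valid),
        "mean_r": float(r.mean()),
        "median_r": float(np.median(r)),
        "hist_edges": edges.tolist(),
        "hist_counts": counts.tolist(),
    }
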