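"""Station meteorology to monthly raster fields.

Temperature and precipitation are spread from the station network onto the
model grid by inverse-distance weighting (IDW). Total monthly solar
radiation is derived from recorded sunshine duration with the
Ångström–Prescott relation

    SOL = (a + b * n/N) * Ra

where n is observed sunshine hours, N the astronomical day length and Ra
extraterrestrial radiation, both from standard solar geometry evaluated at
mid-month and summed over the month. FAO-56 defaults a=0.25, b=0.50.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataValidationError
from .raster_io import MonthlyStack, RasterGrid, StationRecord

__all__ = [
    "MonthlyClimateField",
    "idw_interpolate",
    "solar_from_sunshine",
    "day_length_hours",
    "extraterrestrial_radiation",
    "build_climate_fields",
]

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1


@dataclass
class MonthlyClimateField:
    """Interpolated monthly climate rasters on one shared grid."""

    temperature: MonthlyStack   # degC
    precipitation: MonthlyStack  # mm month-1
    solar: MonthlyStack          # MJ m-2 month-1

    def __post_init__(self) -> None:
        self.temperature.grid.require_same(self.precipitation.grid)
        self.temperature.grid.require_same(self.solar.grid)

    @property
    def grid(self) -> RasterGrid:
        return self.temperature.grid

    @property
    def years(self) -> list[int]:
        return self.temperature.years


# ---------------------------------------------------------------------------
# Solar geometry (FAO-56)

def _mid_month_doy(year: int, month: int) -> int:
    first = sum(calendar.monthrange(year, m)[1] for m in range(1, month))
    return first + calendar.monthrange(year, month)[1] // 2


def _declination(doy: int | np.ndarray) -> np.ndarray:
    return 0.409 * np.sin(2 * np.pi * doy / 365 - 1.39)


def day_length_hours(latitude: float, year: int, month: int) -> float:
    """Astronomical day length (h) at mid-month for the given latitude."""
    if abs(latitude) >= 66.5:
        raise ConfigError(f"latitude {latitude} outside supported range |lat| < 66.5")
    phi = np.deg2rad(latitude)
    delta = _declination(_mid_month_doy(year, month))
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1, 1))
    return float(24 / np.pi * ws)


def extraterrestrial_radiation(latitude: float, year: int, month: int) -> float:
    """Monthly extraterrestrial radiation Ra (MJ m-2 month-1) at mid-month."""
    if abs(latitude) >= 66.5:
        raise ConfigError(f"latitude {latitude} outside supported range |lat| < 66.5")
    phi = np.deg2rad(latitude)
    doy = _mid_month_doy(year, month)
    delta = _declination(doy)
    dr = 1 + 0.033 * np.cos(2 * np.pi * doy / 365)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1, 1))
    ra_daily = (24 * 60 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    return float(ra_daily * calendar.monthrange(year, month)[1])


def solar_from_sunshine(sunshine_hours: float, year: int, month: int,
                        latitude: float, a: float = 0.25, b: float = 0.50) -> float:
    """Monthly total solar radiation (MJ m-2 month-1) from sunshine duration.

    ``sunshine_hours`` is the monthly total of bright-sunshine hours; the
    relative fraction n/N uses the astronomical day length summed over the
    month. Fractions above 1 (possible with noisy records) are clipped to 1
    with a warning.
    """
    if sunshine_hours < 0:
        raise DataValidationError(f"negative sunshine hours: {sunshine_hours}")
    n_days = calendar.monthrange(year, month)[1]
    n_total = day_length_hours(latitude, year, month) * n_days
    frac = sunshine_hours / n_total
    if frac > 1:
        warnings.warn(
            f"sunshine fraction {frac:.3f} > 1 for {year}-{month:02d}; clipping to 1",
            stacklevel=2)
        frac = 1.0
    return (a + b * frac) * extraterrestrial_radiation(latitude, year, month)


# ---------------------------------------------------------------------------
# Inverse-distance weighting

def idw_interpolate(xs: np.ndarray, ys: np.ndarray, values: np.ndarray,
                    grid: RasterGrid, power: float = 2.0) -> np.ndarray:
    """IDW of scattered station values onto every pixel centre.

    Weights are d^-power. A pixel whose footprint contains a station takes
    that station's value exactly (nearest station to the centre wins when a
    pixel contains several); coincident duplicate stations are rejected.
    The output is bounded by the station extremes (positive weights).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    values = np.asarray(values, dtype=float)
    if xs.size == 0:
        raise DataValidationError("IDW requires at least one station")
    if xs.shape != ys.shape or xs.shape != values.shape:
        raise ConfigError("xs, ys, values must have identical shapes")
    pts = np.column_stack([xs, ys])
    if len(np.unique(pts, axis=0)) != len(pts):
        raise DataValidationError("coincident duplicate stations")
    if power <= 0:
        raise ConfigError(f"IDW power must be positive, got {power}")

    px, py = grid.pixel_centers()
    d2 = (px[..., None] - xs) ** 2 + (py[..., None] - ys) ** 2
    with np.errstate(divide="ignore"):
        w = d2 ** (-power / 2.0)
    at_station = d2 == 0
    out = np.empty(grid.shape, dtype=float)
    any_exact = at_station.any(axis=-1)
    w_masked = np.where(any_exact[..., None], 0.0, w)
    with np.errstate(invalid="ignore"):
        out = (w_masked * values).sum(axis=-1) / w_masked.sum(axis=-1)
    # zero-distance rule
    if any_exact.any():
        idx = np.argmax(at_station, axis=-1)
        out[any_exact] = values[idx[any_exact]]
    # containment rule: pixel holding a station takes its value
    dist_to_center = np.full(len(xs), np.inf)
    assigned: dict[tuple[int, int], int] = {}
    for i in range(len(xs)):
        if not grid.contains(xs[i], ys[i]):
            continue
        r, c = grid.index_of(xs[i], ys[i])
        cx = grid.origin_x + (c + 0.5) * grid.pixel_size
        cy = grid.origin_y - (r + 0.5) * grid.pixel_size
        d = (xs[i] - cx) ** 2 + (ys[i] - cy) ** 2
        key = (r, c)
        if key not in assigned or d < dist_to_center[assigned[key]]:
            assigned[key] = i
            dist_to_center[i] = d
    for (r, c), i in assigned.items():
        out[r, c] = values[i]
    return out


# ---------------------------------------------------------------------------
# Field assembly

def build_climate_fields(stations: list[StationRecord], grid: RasterGrid,
                         latitude: float, power: float = 2.0,
                         angstrom_a: float = 0.25, angstrom_b: float = 0.50,
                         ) -> MonthlyClimateField:
    """Interpolate the full station archive into monthly climate rasters.

    Temperature and precipitation are IDW-interpolated per month; sunshine
    duration is IDW-interpolated and then converted to total solar
    radiation with the Ångström–Prescott relation at the configured site
    latitude.
    """
    if not stations:
        raise DataValidationError("no station records")
    years = sorted({r.year for r in stations})
    by_ym: dict[tuple[int, int], list[StationRecord]] = {}
    for r in stations:
        by_ym.setdefault((r.year, r.month), []).append(r)

    shape = (len(years), 12, grid.rows, grid.cols)
    temp = np.full(shape, np.nan)
    precip = np.full(shape, np.nan)
    solar = np.full(shape, np.nan)
    for yi, year in enumerate(years):
        for month in range(1, 13):
            recs = by_ym.get((year, month))
            if not recs:
                continue
            xs = np.array([r.x for r in recs])
            ys = np.array([r.y for r in recs])
            temp[yi, month - 1] = idw_interpolate(
                xs, ys, np.array([r.temp_c for r in recs]), grid, power)
            precip[yi, month - 1] = idw_interpolate(
                xs, ys, np.array([r.precip_mm for r in recs]), grid, power)
            sun = idw_interpolate(
                xs, ys, np.array([r.sunshine_h for r in recs]), grid, power)
            # Ra and N depend only on latitude/month, so convert after IDW
            n_days = calendar.monthrange(year, month)[1]
            n_total = day_length_hours(latitude, year, month) * n_days
            frac = np.clip(sun / n_total, 0.0, 1.0)
            solar[yi, month - 1] = (angstrom_a + angstrom_b * frac) * \
                extraterrestrial_radiation(latitude, year, month)
    return MonthlyClimateField(
        temperature=MonthlyStack(grid, years, temp, "temperature", "degC"),
        precipitation=MonthlyStack(grid, years, precip, "precipitation", "mm"),
        solar=MonthlyStack(grid, years, solar, "solar", "MJ m-2 month-1"),
    )
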