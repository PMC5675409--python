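"""The CASA light-use-efficiency model.

Monthly net primary productivity is estimated as

    NPP(x,t) = APAR(x,t) * eps(x,t)
    APAR(x,t) = SOL(x,t) * FPAR(x,t) * 0.5
    eps(x,t)  = Teps1(x,t) * Teps2(x,t) * Weps(x,t) * eps_max

FPAR is the mean of two linear estimates — one from NDVI, one from the
simple ratio SR = (1+NDVI)/(1−NDVI) — each rescaled between
vegetation-class-specific bounds and clamped to [0.001, 0.95].

The stress scalars follow the standard modified-CASA forms: Teps1 is a
quadratic in the pixel's optimal temperature (the mean temperature of the
month with the year's maximum NDVI), Teps2 a double-logistic in the
departure of monthly temperature from optimal, and Weps = 0.5 + 0.5*EET/PET
with estimated and potential evapotranspiration from a single-layer soil
moisture bucket driven by Thornthwaite PET and monthly precipitation.

Unstressed maximum light-use efficiency eps_max is vegetation-type
specific: 0.542 gC/MJ for grassland and 0.429 gC/MJ for shrubs.

All operations are element-wise over arrays of any shape; NaN marks nodata
and propagates.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np

from .climate_fields import MonthlyClimateField, day_length_hours
from .errors import ConfigError, DataValidationError, NumericalError
from .raster_io import MonthlyStack

__all__ = [
    "VegClassParams",
    "FparConstants",
    "NppSeries",
    "EPS_MAX_GRASSLAND",
    "EPS_MAX_SHRUB",
    "PAR_FRACTION",
    "WINTER_MONTHS",
    "compute_ndvi",
    "composite_monthly",
    "compute_sr",
    "fpar_from_ndvi",
    "fpar_from_sr",
    "compute_fpar",
    "calibrate_class_bounds",
    "temp_stress_1",
    "temp_stress_2",
    "thornthwaite_pet",
    "soil_moisture_et",
    "moisture_stress",
    "light_use_efficiency",
    "compute_apar",
    "compute_npp_month",
    "optimal_temperature",
    "run_casa",
]

EPS_MAX_GRASSLAND = 0.542  # gC MJ-1
EPS_MAX_SHRUB = 0.429      # gC MJ-1
PAR_FRACTION = 0.5         # fraction of SOL usable by vegetation (0.38-0.71 um)
WINTER_MONTHS = (12, 1, 2)
COLD_CUTOFF_C = -10.0      # monthly mean below this shuts down Teps1


@dataclass(frozen=True)
class FparConstants:
    fpar_min: float = 0.001
    fpar_max: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.fpar_min < self.fpar_max <= 1):
            raise ConfigError(f"need 0 <= fpar_min < fpar_max <= 1, got {self}")


@dataclass(frozen=True)
class VegClassParams:
    """Per-vegetation-class calibration: NDVI/SR bounds and eps_max."""

    class_id: int
    ndvi_min: float
    ndvi_max: float
    sr_min: float
    sr_max: float
    eps_max: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.ndvi_min < self.ndvi_max:
            raise ConfigError(f"class {self.class_id}: ndvi_min must be < ndvi_max")
        if not self.sr_min < self.sr_max:
            raise ConfigError(f"class {self.class_id}: sr_min must be < sr_max")
        if self.eps_max <= 0:
            raise ConfigError(f"class {self.class_id}: eps_max must be positive")


@dataclass
class NppSeries:
    """Monthly NPP stack (gC m-2 month-1) with optional diagnostics.

    Winter layers (Dec-Feb) are identically zero: snow cover and dormancy
    preclude production, so annual NPP equals growing-season NPP.
    """

    monthly: MonthlyStack
    diagnostics: dict = field(default_factory=dict)

    @property
    def grid(self):
        return self.monthly.grid

    @property
    def years(self) -> list[int]:
        return self.monthly.years


# ---------------------------------------------------------------------------
# Vegetation indices and FPAR

def compute_ndvi(red, nir):
    """NDVI = (NIR - red) / (NIR + red); nodata where the sum is zero."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0, np.nan, (nir - red) / denom)
    return out


def composite_monthly(layers: np.ndarray) -> np.ndarray:
    """Maximum-value composite of sub-monthly layers (axis 0).

    Per-pixel maximum over the stacked 8-day layers; nodata only where all
    inputs are nodata. MVC suppresses cloud and atmospheric depression of
    the vegetation signal.
    """
    layers = np.asarray(layers, dtype=float)
    if layers.ndim < 1 or layers.shape[0] < 1:
        raise ConfigError("composite needs at least one layer")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmax(layers, axis=0)
    return out


def compute_sr(ndvi):
    """Simple ratio SR = (1 + NDVI) / (1 - NDVI); nodata at NDVI = 1."""
    ndvi = np.asarray(ndvi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ndvi == 1, np.nan, (1 + ndvi) / (1 - ndvi))
    return out


def _linear_rescale(value, lo, hi, c: FparConstants):
    scaled = (np.asarray(value, dtype=float) - lo) / (hi - lo) \
        * (c.fpar_max - c.fpar_min) + c.fpar_min
    return np.clip(scaled, c.fpar_min, c.fpar_max)


def fpar_from_ndvi(ndvi, params: VegClassParams, c: FparConstants = FparConstants()):
    """FPAR from NDVI: linear between class bounds, clamped to the FPAR range."""
    return _linear_rescale(ndvi, params.ndvi_min, params.ndvi_max, c)


def fpar_from_sr(sr, params: VegClassParams, c: FparConstants = FparConstants()):
    """FPAR from SR: linear between class SR bounds, clamped."""
    return _linear_rescale(sr, params.sr_min, params.sr_max, c)


def compute_fpar(fpar_ndvi, fpar_sr):
    """Final FPAR: arithmetic mean of the NDVI- and SR-based estimates."""
    return (np.asarray(fpar_ndvi, dtype=float) + np.asarray(fpar_sr, dtype=float)) / 2.0


def calibrate_class_bounds(ndvi_history: np.ndarray, landcover: np.ndarray,
                           eps_max_by_class: dict[int, float],
                           pct_lo: float = 5.0, pct_hi: float = 95.0,
                           names: dict[int, str] | None = None,
                           min_samples: int = 20) -> dict[int, VegClassParams]:
    """Derive per-class NDVI bounds from the NDVI history and convert to SR.

    NDVI bounds are the configured percentiles (default 5/95) of all valid
    NDVI samples of the class's pixels; SR bounds are SR evaluated at those
    NDVI percentiles.
    """
    ndvi_history = np.asarray(ndvi_history, dtype=float)
    landcover = np.asarray(landcover)
    out: dict[int, VegClassParams] = {}
    for class_id, eps_max in eps_max_by_class.items():
        mask = landcover == class_id
        samples = ndvi_history[..., mask]
        samples = samples[np.isfinite(samples)]
        if samples.size < min_samples:
            raise DataValidationError(
                f"class {class_id}: only {samples.size} valid NDVI samples "
                f"(need >= {min_samples})")
        lo, hi = np.percentile(samples, [pct_lo, pct_hi])
        if not lo < hi:
            raise DataValidationError(
                f"class {class_id}: degenerate NDVI bounds ({lo} == {hi})")
        out[class_id] = VegClassParams(
            class_id=class_id, ndvi_min=float(lo), ndvi_max=float(hi),
            sr_min=float(compute_sr(lo)), sr_max=float(compute_sr(hi)),
            eps_max=eps_max, name=(names or {}).get(class_id, ""))
    return out


# ---------------------------------------------------------------------------
# Stress scalars

def temp_stress_1(t_opt, t_month=None):
    """Teps1 = 0.8 + 0.02*t_opt - 0.0005*t_opt^2, floored at 0.

    Where the month's mean temperature is at or below -10 degC the scalar
    is 0 (no production in deep cold).
    """
    t_opt = np.asarray(t_opt, dtype=float)
    out = np.clip(0.8 + 0.02 * t_opt - 0.0005 * t_opt ** 2, 0.0, None)
    if t_month is not None:
        t_month = np.asarray(t_month, dtype=float)
        out = np.where(t_month <= COLD_CUTOFF_C, 0.0, out)
    return out


def _teps2_raw(t, t_opt):
    return 1.1814 / (1 + np.exp(0.2 * (t_opt - 10 - t))) \
                  / (1 + np.exp(0.3 * (-t_opt - 10 + t)))


def temp_stress_2(t, t_opt):
    """Teps2: double-logistic response of efficiency to monthly temperature.

    Above t_opt + 10 the value is capped at the scalar's value at t_opt
    (the cap only binds if the raw curve would exceed it there).
    """
    t = np.asarray(t, dtype=float)
    t_opt = np.asarray(t_opt, dtype=float)
    raw = _teps2_raw(t, t_opt)
    hot = t > t_opt + 10
    return np.where(hot, np.minimum(raw, _teps2_raw(t_opt, t_opt)), raw)


def thornthwaite_pet(temp_monthly: np.ndarray, latitude: float, year: int) -> np.ndarray:
    """Thornthwaite potential evapotranspiration (mm month-1).

    ``temp_monthly`` has shape (12, ...) of monthly mean temperature for one
    calendar year. Uses the annual heat index per pixel and a day-length /
    month-length correction.
    """
    t = np.asarray(temp_monthly, dtype=float)
    if t.shape[0] != 12:
        raise ConfigError("thornthwaite_pet expects 12 monthly layers")
    t_pos = np.clip(t, 0.0, None)
    heat_index = ((t_pos / 5.0) ** 1.514).sum(axis=0)
    a = (6.75e-7 * heat_index ** 3 - 7.71e-5 * heat_index ** 2
         + 1.792e-2 * heat_index + 0.49239)
    pet = np.zeros_like(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        for m in range(12):
            n_days = calendar.monthrange(year, m + 1)[1]
            corr = day_length_hours(latitude, year, m + 1) / 12.0 * n_days / 30.0
            base = np.where(heat_index > 0,
                            16.0 * (10.0 * t_pos[m] / np.where(heat_index > 0, heat_index, 1.0)) ** a,
                            0.0)
            pet[m] = np.where(t[m] > 0, base * corr, 0.0)
    nan_mask = np.isnan(t).any(axis=0)
    if t.ndim > 1:
        pet[:, nan_mask] = np.nan
    elif nan_mask:
        pet[:] = np.nan
    return pet


def soil_moisture_et(precip: np.ndarray, pet: np.ndarray,
                     capacity: float = 100.0,
                     initial_fraction: float = 0.5) -> np.ndarray:
    """Estimated evapotranspiration from a single-layer soil bucket.

    Iterates chronologically over the leading axis: the month's EET is the
    smaller of PET and the available supply (precipitation plus stored soil
    water); the residual recharges the bucket up to ``capacity``, the rest
    runs off. The bucket starts at ``initial_fraction`` of capacity.
    """
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if precip.shape != pet.shape:
        raise ConfigError("precip and pet shapes differ")
    if capacity <= 0:
        raise ConfigError("bucket capacity must be positive")
    soil = np.full(precip.shape[1:], capacity * initial_fraction)
    eet = np.zeros_like(precip)
    for m in range(precip.shape[0]):
        p = np.nan_to_num(precip[m], nan=0.0)
        pe = np.nan_to_num(pet[m], nan=0.0)
        supply = p + soil
        eet[m] = np.minimum(pe, supply)
        soil = np.clip(soil + p - eet[m], 0.0, capacity)
        eet[m] = np.where(np.isnan(precip[m]) | np.isnan(pet[m]), np.nan, eet[m])
    return eet


def moisture_stress(eet, pet):
    """Weps = 0.5 + 0.5 * EET/PET, clamped to [0.5, 1]; PET=0 -> 0.5."""
    eet = np.asarray(eet, dtype=float)
    pet = np.asarray(pet, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pet > 0, eet / pet, 0.0)
    out = 0.5 + 0.5 * np.clip(ratio, 0.0, 1.0)
    return np.where(np.isnan(eet) | np.isnan(pet), np.nan, out)


def light_use_efficiency(t_eps1, t_eps2, w_eps, eps_max):
    """eps = Teps1 * Teps2 * Weps * eps_max (gC MJ-1)."""
    return (np.asarray(t_eps1, dtype=float) * np.asarray(t_eps2, dtype=float)
            * np.asarray(w_eps, dtype=float) * np.asarray(eps_max, dtype=float))


def compute_apar(sol, fpar):
    """APAR = SOL * FPAR * 0.5 (MJ m-2 month-1)."""
    return np.asarray(sol, dtype=float) * np.asarray(fpar, dtype=float) * PAR_FRACTION


def compute_npp_month(apar, eps):
    """Monthly NPP = APAR * eps (gC m-2 month-1); nodata propagates."""
    return np.asarray(apar, dtype=float) * np.asarray(eps, dtype=float)


def optimal_temperature(ndvi_year: np.ndarray, temp_year: np.ndarray) -> np.ndarray:
    """Per-pixel optimal temperature for one year.

    The mean temperature of the month in which NDVI peaks that year
    (standard CASA convention). Shapes (12, rows, cols) -> (rows, cols).
    """
    ndvi_year = np.asarray(ndvi_year, dtype=float)
    temp_year = np.asarray(temp_year, dtype=float)
    filled = np.where(np.isfinite(ndvi_year), ndvi_year, -np.inf)
    best = np.argmax(filled, axis=0)
    t_opt = np.take_along_axis(temp_year, best[None], axis=0)[0]
    t_opt = np.where(np.isfinite(filled).any(axis=0), t_opt, np.nan)
    return t_opt


# ---------------------------------------------------------------------------
# Full model driver

def run_casa(ndvi: MonthlyStack, climate: MonthlyClimateField,
             landcover: np.ndarray, class_params: dict[int, VegClassParams],
             constants: FparConstants = FparConstants(),
             latitude: float = 44.0, bucket_capacity: float = 100.0,
             keep_diagnostics: bool = False) -> NppSeries:
    """Run the full monthly CASA chain on a calibrated world.

    Pixels whose land-cover class has no parameters (e.g. non-vegetated)
    are nodata throughout. December-February NPP is forced to zero.
    """
    ndvi.grid.require_same(climate.grid)
    if ndvi.years != climate.years:
        raise DataValidationError(
            f"NDVI years {ndvi.years} differ from climate years {climate.years}")
    landcover = np.asarray(landcover)
    if landcover.shape != ndvi.grid.shape:
        raise DataValidationError("landcover shape does not match grid")

    shape = ndvi.data.shape  # (Y, 12, r, c)
    veg_mask = np.isin(landcover, list(class_params))
    ndvi_min = np.full(ndvi.grid.shape, np.nan)
    ndvi_max = np.full(ndvi.grid.shape, np.nan)
    sr_min = np.full(ndvi.grid.shape, np.nan)
    sr_max = np.full(ndvi.grid.shape, np.nan)
    eps_max = np.full(ndvi.grid.shape, np.nan)
    for cid, p in class_params.items():
        m = landcover == cid
        ndvi_min[m], ndvi_max[m] = p.ndvi_min, p.ndvi_max
        sr_min[m], sr_max[m] = p.sr_min, p.sr_max
        eps_max[m] = p.eps_max

    # FPAR for every layer
    sr = compute_sr(ndvi.data)
    f_ndvi = np.clip((ndvi.data - ndvi_min) / (ndvi_max - ndvi_min)
                     * (constants.fpar_max - constants.fpar_min) + constants.fpar_min,
                     constants.fpar_min, constants.fpar_max)
    f_sr = np.clip((sr - sr_min) / (sr_max - sr_min)
                   * (constants.fpar_max - constants.fpar_min) + constants.fpar_min,
                   constants.fpar_min, constants.fpar_max)
    fpar = compute_fpar(f_ndvi, f_sr)

    temp = climate.temperature.data
    precip = climate.precipitation.data
    sol = climate.solar.data

    t_eps1 = np.empty(shape)
    t_eps2 = np.empty(shape)
    pet = np.empty(shape)
    for yi, year in enumerate(ndvi.years):
        t_opt = optimal_temperature(ndvi.data[yi], temp[yi])
        t_eps1[yi] = temp_stress_1(t_opt[None], temp[yi])
        t_eps2[yi] = temp_stress_2(temp[yi], t_opt[None])
        pet[yi] = thornthwaite_pet(temp[yi], latitude, year)

    flat = lambda a: a.reshape(-1, *ndvi.grid.shape)
    eet = soil_moisture_et(flat(precip), flat(pet), capacity=bucket_capacity)
    w_eps = moisture_stress(eet, flat(pet)).reshape(shape)

    eps = light_use_efficiency(t_eps1, t_eps2, w_eps, eps_max)
    apar = compute_apar(sol, fpar)
    npp = np.clip(compute_npp_month(apar, eps), 0.0, None)
    npp[:, [m - 1 for m in WINTER_MONTHS]] = np.where(
        np.isnan(npp[:, [m - 1 for m in WINTER_MONTHS]]), np.nan, 0.0)
    npp[..., ~veg_mask] = np.nan

    if not np.isfinite(npp[..., veg_mask]).any():
        raise NumericalError("CASA produced no finite NPP values")

    series = NppSeries(monthly=ndvi.copy_like(npp, "npp", "gC m-2 month-1"))
    if keep_diagnostics:
        series.diagnostics.update(fpar=fpar, eps=eps, apar=apar,
                                  t_eps1=t_eps1, t_eps2=t_eps2, w_eps=w_eps)
    return series
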