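"""Synthetic study-area generator with known ground-truth couplings.

Builds a self-consistent world emulating the semi-arid steppe setting the
pipeline targets: a west-to-east moisture/productivity gradient, annual
precipitation around 295 mm concentrated in July-September, a continental
temperature regime around a 3.36 degC annual mean, a nine-station monthly
meteorological network, a nine-county block partition, clip-plot biomass
observations, and yearly livestock counts.

Latent productivity is multiplicative:

    rel(x, m, yr) = template(m) * base(x)
                    * (1 + g_p * precip_anomaly(x, yr))
                    * (1 + g_t * temp_anomaly(yr))
                    * (1 + noise_sd * z)

where ``template`` is a unimodal seasonal greenness curve peaking in July,
``base`` carries the west->east gradient, and the anomalies are the
fractional annual-precipitation departure and the yearly temperature
departure (degC). NDVI is the scaled latent curve and surface reflectance
is back-solved from it (red fixed at 0.08), so every downstream estimate
can be checked against a known truth. Because the coupling is linear in
annual precipitation, sign-recovery expectations are analytic: with
noise_sd = 0 and g_t = 0 the per-pixel correlation of latent productivity
with precipitation is exactly 1.

Yearly temperature anomalies are drawn with a configurable correlation to
the precipitation anomalies (wet years cooler by default), so with
g_t = 0 temperature influences productivity only through precipitation —
the regime in which a partial-correlation analysis should flatten the
apparent temperature effect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .climate_fields import day_length_hours
from .errors import ConfigError, DataValidationError
from .raster_io import (MonthlyStack, RasterGrid, StationRecord,
                        write_raster, write_raster_stack, write_stations,
                        stations_to_frame)

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "TruthRecord",
    "make_world",
    "make_validation_plots",
    "make_livestock_series",
    "write_world",
    "CLASS_NONVEG",
    "CLASS_GRASSLAND",
    "CLASS_SHRUB",
    "MONTH_PRECIP_WEIGHTS",
    "NDVI_TEMPLATE",
]

CLASS_NONVEG = 0
CLASS_GRASSLAND = 1
CLASS_SHRUB = 2

# Monthly share of annual precipitation; July-September carry 0.56 of the
# total (rain concentrated in Jul/Aug/Sep).
MONTH_PRECIP_WEIGHTS = np.array(
    [0.010, 0.010, 0.020, 0.040, 0.060, 0.090,
     0.200, 0.210, 0.150, 0.090, 0.070, 0.050])

# Unimodal seasonal greenness template, peak normalised to 1 in July.
NDVI_TEMPLATE = np.array(
    [0.05, 0.06, 0.15, 0.35, 0.60, 0.85, 1.00, 0.95, 0.70, 0.40, 0.15, 0.06])

_WINTER_IDX = [11, 0, 1]  # Dec, Jan, Feb


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    n_years: int = 13
    start_year: int = 2001
    grid_shape: tuple[int, int] = (20, 20)
    pixel_size: float = 500.0
    n_stations: int = 9
    precip_annual_mean: float = 295.0   # mm
    precip_gradient: float = 0.5        # fractional change west->east
    temp_annual_mean: float = 3.36      # degC
    npp_precip_coupling: float = 0.8    # gain on fractional precip anomaly
    npp_temp_coupling: float = 0.0      # gain per degC of yearly temp anomaly
    noise_sd: float = 0.05              # fractional multiplicative noise
    # secondary shape parameters
    temp_seasonal_amplitude: float = 19.0  # degC, winter-summer half-range
    temp_year_sd: float = 0.9              # degC sd of yearly anomalies
    temp_precip_corr: float = -0.6         # corr(yearly temp, yearly precip)
    precip_year_sd: float = 0.15           # fractional sd of yearly anomalies
    precip_pixel_sd: float = 0.05          # fractional pixel-year jitter
    sunshine_frac_mean: float = 0.68
    sunshine_frac_sd: float = 0.05
    peak_ndvi: float = 0.65
    npp_scale: float = 240.0               # gC m-2 yr-1 mean latent annual NPP
    shrub_fraction: float = 0.15
    nonveg_fraction: float = 0.05
    periods_per_month: int = 2             # sub-monthly reflectance layers
    latitude: float = 44.0
    county_blocks: tuple[int, int] = (3, 3)

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ConfigError(f"n_years must be >= 2, got {self.n_years}")
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ConfigError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.n_stations < 2:
            raise ConfigError(f"n_stations must be >= 2, got {self.n_stations}")
        if self.precip_annual_mean <= 0:
            raise ConfigError("precip_annual_mean must be positive")
        if self.npp_precip_coupling < 0:
            raise ConfigError("npp_precip_coupling must be >= 0")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")
        if self.periods_per_month < 1:
            raise ConfigError("periods_per_month must be >= 1")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class TruthRecord:
    """Latent productivity truth and the generating couplings."""

    npp_monthly: MonthlyStack          # latent NPP, winter zeroed (gC m-2 mo-1)
    rel: np.ndarray                    # relative productivity (Y,12,r,c)
    precip_annual: np.ndarray          # (Y, r, c) mm
    temp_year_anomaly: np.ndarray      # (Y,) degC
    couplings: dict = field(default_factory=dict)

    def annual_npp(self) -> np.ndarray:
        return self.npp_monthly.data.sum(axis=1)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    grid: RasterGrid
    landcover: np.ndarray              # (r, c) int class raster
    counties: np.ndarray               # (r, c) int, 1..n_counties
    red: np.ndarray                    # (Y, 12, P, r, c) reflectance
    nir: np.ndarray
    ndvi: MonthlyStack                 # the NDVI used to build the truth
    temperature: MonthlyStack          # generating temperature field
    precipitation: MonthlyStack        # generating precipitation field
    stations: list[StationRecord]
    station_xy: np.ndarray             # (n_stations, 2)
    truth: TruthRecord
    plots: pd.DataFrame | None = None
    livestock: pd.DataFrame | None = None


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  coarse: int = 4) -> np.ndarray:
    """Smooth random surface in [0,1] rank space for land-cover patches."""
    rows, cols = shape
    cr = max(2, min(coarse, rows))
    cc = max(2, min(coarse, cols))
    base = rng.normal(size=(cr, cc))
    ry = np.linspace(0, cr - 1, rows)
    rx = np.linspace(0, cc - 1, cols)
    # bilinear upsample
    y0 = np.floor(ry).astype(int)
    x0 = np.floor(rx).astype(int)
    y1 = np.minimum(y0 + 1, cr - 1)
    x1 = np.minimum(x0 + 1, cc - 1)
    fy = (ry - y0)[:, None]
    fx = (rx - x0)[None, :]
    up = (base[np.ix_(y0, x0)] * (1 - fy) * (1 - fx)
          + base[np.ix_(y1, x0)] * fy * (1 - fx)
          + base[np.ix_(y0, x1)] * (1 - fy) * fx
          + base[np.ix_(y1, x1)] * fy * fx)
    up = up + 0.15 * rng.normal(size=shape)
    order = up.ravel().argsort().argsort()
    return (order / max(order.size - 1, 1)).reshape(shape)


def _station_positions(cfg: WorldConfig, grid: RasterGrid,
                       rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform jittered grid of station coordinates inside the grid."""
    k = int(np.ceil(np.sqrt(cfg.n_stations)))
    width = grid.cols * grid.pixel_size
    height = grid.rows * grid.pixel_size
    xs, ys = [], []
    for i in range(k):
        for j in range(k):
            if len(xs) >= cfg.n_stations:
                break
            cx = (j + 0.5) / k * width
            cy = (i + 0.5) / k * height
            jx = rng.uniform(-0.25, 0.25) / k * width
            jy = rng.uniform(-0.25, 0.25) / k * height
            xs.append(grid.origin_x + np.clip(cx + jx, 1e-6, width - 1e-6))
            ys.append(grid.origin_y - np.clip(cy + jy, 1e-6, height - 1e-6))
    return np.column_stack([xs, ys])


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full synthetic world; deterministic for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    grid = RasterGrid(rows=rows, cols=cols, origin_x=0.0,
                      origin_y=rows * cfg.pixel_size,
                      pixel_size=cfg.pixel_size)
    years = cfg.years
    ny = cfg.n_years

    # --- land cover and counties -----------------------------------------
    rank = _smooth_field(rng, (rows, cols))
    landcover = np.full((rows, cols), CLASS_GRASSLAND, dtype=np.int16)
    landcover[rank < cfg.nonveg_fraction] = CLASS_NONVEG
    landcover[(rank >= cfg.nonveg_fraction)
              & (rank < cfg.nonveg_fraction + cfg.shrub_fraction)] = CLASS_SHRUB
    br, bc = cfg.county_blocks
    county_row = np.minimum(np.arange(rows) * br // rows, br - 1)
    county_col = np.minimum(np.arange(cols) * bc // cols, bc - 1)
    counties = (county_row[:, None] * bc + county_col[None, :] + 1).astype(np.int16)

    # --- precipitation ----------------------------------------------------
    col_frac = (np.arange(cols) + 0.5) / cols
    base = cfg.precip_annual_mean * (1 + cfg.precip_gradient * (col_frac - 0.5))
    base = np.broadcast_to(base, (rows, cols))
    z_yr = rng.normal(size=ny)
    year_factor = np.clip(1 + cfg.precip_year_sd * z_yr, 0.3, None)
    jitter = cfg.precip_pixel_sd * rng.normal(size=(ny, rows, cols))
    precip_annual = base[None] * year_factor[:, None, None] * np.clip(1 + jitter, 0.1, None)
    precip_monthly = precip_annual[:, None] * MONTH_PRECIP_WEIGHTS[None, :, None, None]

    # --- temperature (spatially uniform continental cycle) ----------------
    months = np.arange(1, 13)
    season_shape = -np.cos(2 * np.pi * (months - 0.5) / 12)
    z_t = rng.normal(size=ny)
    rho = np.clip(cfg.temp_precip_corr, -1.0, 1.0)
    # Condition the yearly temperature anomalies so the configured
    # temperature-precipitation correlation is realised exactly in-sample:
    # with only ~13 years a free draw scatters far from the target, which
    # would make the world express a coupling other than the configured one.
    if ny >= 3 and np.std(z_yr) > 0 and abs(rho) < 1:
        zp = (z_yr - z_yr.mean()) / z_yr.std()
        resid = z_t - (z_t @ zp) / (zp @ zp) * zp
        if np.std(resid) > 0:
            zperp = (resid - resid.mean()) / resid.std()
            temp_anom = cfg.temp_year_sd * (rho * zp + np.sqrt(1 - rho ** 2) * zperp)
        else:
            temp_anom = cfg.temp_year_sd * rho * zp
    else:
        temp_anom = cfg.temp_year_sd * (rho * z_yr + np.sqrt(1 - rho ** 2) * z_t)
    temp_monthly = (cfg.temp_annual_mean
                    + cfg.temp_seasonal_amplitude * season_shape[None, :]
                    + temp_anom[:, None])
    temp_field = np.broadcast_to(
        temp_monthly[:, :, None, None], (ny, 12, rows, cols)).copy()

    # --- latent productivity ----------------------------------------------
    precip_anom = precip_annual / (base[None] * 1.0) - 1.0
    coupling = np.clip(
        (1 + cfg.npp_precip_coupling * precip_anom)
        * (1 + cfg.npp_temp_coupling * temp_anom[:, None, None]), 0.0, None)
    noise = (np.clip(1 + cfg.noise_sd * rng.normal(size=(ny, 12, rows, cols)), 0.0, None)
             if cfg.noise_sd > 0 else np.ones((ny, 12, rows, cols)))
    base_rel = base / cfg.precip_annual_mean
    rel = (NDVI_TEMPLATE[None, :, None, None] * base_rel[None, None]
           * coupling[:, None] * noise)
    veg = landcover != CLASS_NONVEG
    rel[..., ~veg] = 0.0

    grow_norm = NDVI_TEMPLATE.sum() - NDVI_TEMPLATE[_WINTER_IDX].sum()
    npp_truth = cfg.npp_scale * rel / grow_norm
    npp_truth[:, _WINTER_IDX] = 0.0
    npp_truth[..., ~veg] = 0.0

    ndvi = np.clip(cfg.peak_ndvi * rel, 0.02, 0.92)
    ndvi[..., ~veg] = 0.05

    # --- reflectance back-solved from NDVI --------------------------------
    np_periods = cfg.periods_per_month
    best = rng.integers(0, np_periods, size=(ny, 12, rows, cols))
    degrade = np.abs(rng.normal(0.0, 0.08, size=(ny, 12, np_periods, rows, cols)))
    ndvi_periods = ndvi[:, :, None] - degrade
    take_best = best[:, :, None] == np.arange(np_periods)[None, None, :, None, None]
    ndvi_periods = np.where(take_best, ndvi[:, :, None], ndvi_periods)
    ndvi_periods = np.clip(ndvi_periods, -0.5, 0.92)
    red = np.full_like(ndvi_periods, 0.08)
    nir = red * (1 + ndvi_periods) / (1 - ndvi_periods)

    # --- station records ---------------------------------------------------
    station_xy = _station_positions(cfg, grid, rng)
    sun_base = np.clip(cfg.sunshine_frac_mean
                       + cfg.sunshine_frac_sd * rng.normal(size=(ny, 12)), 0.25, 0.95)
    sun_station_noise = 0.02 * rng.normal(size=(len(station_xy), ny, 12))
    records: list[StationRecord] = []
    import calendar as _cal
    for si, (sx, sy) in enumerate(station_xy):
        r, c = grid.index_of(sx, sy)
        for yi, year in enumerate(years):
            for mi in range(12):
                frac = float(np.clip(sun_base[yi, mi] + sun_station_noise[si, yi, mi],
                                     0.05, 1.0))
                n_days = _cal.monthrange(year, mi + 1)[1]
                sun_h = frac * day_length_hours(cfg.latitude, year, mi + 1) * n_days
                records.append(StationRecord(
                    station_id=f"station_{si + 1}",
                    x=float(sx), y=float(sy), year=year, month=mi + 1,
                    temp_c=float(temp_field[yi, mi, r, c]),
                    precip_mm=float(precip_monthly[yi, mi, r, c]),
                    sunshine_h=float(sun_h)))

    truth = TruthRecord(
        npp_monthly=MonthlyStack(grid, years, npp_truth, "npp_truth", "gC m-2 month-1"),
        rel=rel,
        precip_annual=precip_annual,
        temp_year_anomaly=temp_anom,
        couplings={"npp_precip_coupling": cfg.npp_precip_coupling,
                   "npp_temp_coupling": cfg.npp_temp_coupling,
                   "noise_sd": cfg.noise_sd,
                   "temp_precip_corr": cfg.temp_precip_corr},
    )
    world = SyntheticWorld(
        config=cfg, grid=grid, landcover=landcover, counties=counties,
        red=red, nir=nir,
        ndvi=MonthlyStack(grid, years, ndvi, "ndvi", ""),
        temperature=MonthlyStack(grid, years, temp_field, "temperature", "degC"),
        precipitation=MonthlyStack(grid, years, precip_monthly, "precipitation", "mm"),
        stations=records, station_xy=station_xy, truth=truth)
    world.plots = make_validation_plots(world, n_plots=46, obs_noise_sd=15.0)
    world.livestock = make_livestock_series(world, trend=-3000.0)
    return world


def make_validation_plots(world: SyntheticWorld, n_plots: int,
                          obs_noise_sd: float = 0.0,
                          sample_year: int | None = None,
                          through_month: int = 7,
                          agb_fraction: float = 0.25) -> pd.DataFrame:
    """Clip-plot biomass observations consistent with the latent truth.

    Total dry biomass at each plot equals latent NPP (summed January to the
    sampling month) divided by the 0.475 carbon coefficient, plus Gaussian
    observation noise of sd ``obs_noise_sd`` (g m-2), so a noiseless table
    converts back to latent NPP exactly. Plots fall on vegetated pixels.
    """
    if n_plots < 1:
        raise ConfigError(f"n_plots must be >= 1, got {n_plots}")
    if obs_noise_sd < 0:
        raise ConfigError("obs_noise_sd must be >= 0")
    cfg = world.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    years = cfg.years
    if sample_year is None:
        sample_year = years[min(10, len(years) - 1)]
    if sample_year not in years:
        raise ConfigError(f"sample_year {sample_year} outside simulated span")
    yi = years.index(sample_year)
    veg_rows, veg_cols = np.nonzero(world.landcover != CLASS_NONVEG)
    if veg_rows.size == 0:
        raise DataValidationError("no vegetated pixels to place plots on")
    pick = rng.choice(veg_rows.size, size=min(n_plots, veg_rows.size), replace=False)
    if n_plots > veg_rows.size:  # sample with replacement beyond unique pixels
        extra = rng.choice(veg_rows.size, size=n_plots - veg_rows.size, replace=True)
        pick = np.concatenate([pick, extra])
    grid = world.grid
    cum = world.truth.npp_monthly.data[yi, :through_month].sum(axis=0)
    rows = []
    for i, k in enumerate(pick):
        r, c = veg_rows[k], veg_cols[k]
        jx, jy = rng.uniform(-0.4, 0.4, size=2) * grid.pixel_size
        x = grid.origin_x + (c + 0.5) * grid.pixel_size + jx
        y = grid.origin_y - (r + 0.5) * grid.pixel_size + jy
        if not grid.contains(x, y):
            raise DataValidationError(f"plot at ({x}, {y}) falls outside the grid")
        total_biomass = cum[r, c] / 0.475
        if obs_noise_sd > 0:
            total_biomass = max(total_biomass + rng.normal(0.0, obs_noise_sd), 0.0)
        rows.append({
            "plot_id": f"plot_{i + 1:03d}", "x": x, "y": y,
            "year": sample_year, "month": through_month,
            "agb": agb_fraction * total_biomass,
            "bgb": (1 - agb_fraction) * total_biomass,
        })
    return pd.DataFrame(rows)


def make_livestock_series(world: SyntheticWorld, trend: float = 0.0) -> pd.DataFrame:
    """Yearly standard-sheep counts per county; linear trend, clipped at 0."""
    cfg = world.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    county_ids = sorted(int(c) for c in np.unique(world.counties))
    base = rng.uniform(1.0e5, 4.0e5, size=len(county_ids))
    rows = []
    for ci, cid in enumerate(county_ids):
        for yi, year in enumerate(cfg.years):
            count = max(base[ci] + trend * yi, 0.0)
            rows.append({"county": f"county_{cid}", "year": year,
                         "standard_sheep": count})
    return pd.DataFrame(rows)


def write_world(world: SyntheticWorld, directory: str | os.PathLike) -> None:
    """Export the world in exactly the formats the pipeline consumes.

    Reflectance goes out as one monthly GeoTIFF stack per sub-monthly
    period and band (red_p0.tif, nir_p0.tif, ...); land cover, counties and
    the latent-truth NPP as rasters; stations/plots/livestock as CSV; the
    configuration as YAML.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    cfg = world.config
    grid = world.grid
    with open(os.path.join(directory, "config.yaml"), "w") as fh:
        yaml.safe_dump({"world": _config_dict(cfg)}, fh, sort_keys=True)
    write_raster(world.landcover.astype(float), grid,
                 os.path.join(directory, "landcover.tif"), variable="landcover")
    write_raster(world.counties.astype(float), grid,
                 os.path.join(directory, "counties.tif"), variable="county")
    for p in range(cfg.periods_per_month):
        for name, arr in (("red", world.red), ("nir", world.nir)):
            stack = MonthlyStack(grid, cfg.years, arr[:, :, p], name, "reflectance")
            write_raster_stack(stack, os.path.join(directory, f"{name}_p{p}.tif"))
    write_raster_stack(world.truth.npp_monthly,
                       os.path.join(directory, "truth_npp.tif"))
    write_stations(world.stations, os.path.join(directory, "stations.csv"))
    if world.plots is not None:
        tmp = os.path.join(directory, "plots.csv.part")
        world.plots.to_csv(tmp, index=False)
        os.replace(tmp, os.path.join(directory, "plots.csv"))
    if world.livestock is not None:
        tmp = os.path.join(directory, "livestock.csv.part")
        world.livestock.to_csv(tmp, index=False)
        os.replace(tmp, os.path.join(directory, "livestock.csv"))


def _config_dict(cfg: WorldConfig) -> dict:
    d = asdict(cfg)
    d["grid_shape"] = list(cfg.grid_shape)
    d["county_blocks"] = list(cfg.county_blocks)
    return d
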