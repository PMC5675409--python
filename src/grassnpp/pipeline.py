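"""Stage orchestration over a workspace directory.

Each stage reads and writes only the documented file formats inside one
workspace, so stages can be run separately or chained by ``run_all``.
Outputs are written atomically (temp file + rename), so a failed stage
never leaves partial files in place.

Workspace layout::

    world/            synthetic inputs (reflectance, stations, land cover,
                      plots, livestock, truth)
    ndvi.tif          monthly maximum-value-composite NDVI
    temperature.tif, precipitation.tif, solar.tif
    npp_monthly.tif   CASA monthly NPP
    npp_annual_<y>.tif, npp_<season>_<y>.tif
    regional_series.csv, trend_acf.json
    validation.json, validation_pairs.csv
    attribution/      r/p rasters, summaries, county_table.csv
"""

from __future__ import annotations

import glob
import json
import os

import numpy as np
import pandas as pd

from . import aggregation, casa_core, climate_attribution, climate_fields
from . import raster_io, synthetic, validation as validation_mod
from .config import PipelineConfig
from .errors import MissingInputError
from .synthetic import CLASS_GRASSLAND, CLASS_SHRUB

__all__ = ["simulate", "ndvi_stage", "interpolate_stage", "npp_stage",
           "aggregate_stage", "validate_stage", "attribute_stage", "run_all"]

CLASS_IDS = {"grassland": CLASS_GRASSLAND, "shrub": CLASS_SHRUB}


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise MissingInputError(f"required input not found: {path}")
    return path


def _write_json(obj, path: str) -> None:
    tmp = path + ".part"
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def _write_csv(frame: pd.DataFrame, path: str) -> None:
    tmp = path + ".part"
    frame.to_csv(tmp, index=False, float_format="%.10g")
    os.replace(tmp, path)


def simulate(cfg: PipelineConfig, workspace: str, seed: int | None = None) -> str:
    """Generate the synthetic world and write it under workspace/world."""
    world_cfg = cfg.world
    if seed is not None:
        from dataclasses import replace
        world_cfg = replace(world_cfg, seed=seed)
    world = synthetic.make_world(world_cfg)
    out = os.path.join(workspace, "world")
    synthetic.write_world(world, out)
    return out


def ndvi_stage(cfg: PipelineConfig, workspace: str) -> str:
    """NDVI per sub-monthly period, then monthly maximum-value composite."""
    wdir = os.path.join(workspace, "world")
    red_paths = sorted(glob.glob(os.path.join(wdir, "red_p*.tif")))
    if not red_paths:
        raise MissingInputError(
            f"required input not found: {os.path.join(wdir, 'red_p*.tif')}")
    period_ndvi = []
    grid = years = None
    for red_path in red_paths:
        nir_path = _require(red_path.replace("red_p", "nir_p"))
        red = raster_io.read_raster_stack(red_path)
        nir = raster_io.read_raster_stack(nir_path)
        red.grid.require_same(nir.grid)
        period_ndvi.append(casa_core.compute_ndvi(red.data, nir.data))
        grid, years = red.grid, red.years
    monthly = casa_core.composite_monthly(np.stack(period_ndvi))
    out = os.path.join(workspace, "ndvi.tif")
    raster_io.write_raster_stack(
        raster_io.MonthlyStack(grid, years, monthly, "ndvi", ""), out)
    return out


def interpolate_stage(cfg: PipelineConfig, workspace: str) -> dict[str, str]:
    """IDW temperature/precipitation and Angstrom-Prescott solar rasters."""
    stations = raster_io.read_stations(
        _require(os.path.join(workspace, "world", "stations.csv")))
    ndvi = raster_io.read_raster_stack(_require(os.path.join(workspace, "ndvi.tif")))
    fields = climate_fields.build_climate_fields(
        stations, ndvi.grid, latitude=cfg.latitude,
        power=cfg.interpolation_power,
        angstrom_a=cfg.angstrom_a, angstrom_b=cfg.angstrom_b)
    paths = {}
    for name, stack in (("temperature", fields.temperature),
                        ("precipitation", fields.precipitation),
                        ("solar", fields.solar)):
        path = os.path.join(workspace, f"{name}.tif")
        raster_io.write_raster_stack(stack, path)
        paths[name] = path
    return paths


def _read_climate(workspace: str) -> climate_fields.MonthlyClimateField:
    return climate_fields.MonthlyClimateField(
        temperature=raster_io.read_raster_stack(
            _require(os.path.join(workspace, "temperature.tif"))),
        precipitation=raster_io.read_raster_stack(
            _require(os.path.join(workspace, "precipitation.tif"))),
        solar=raster_io.read_raster_stack(
            _require(os.path.join(workspace, "solar.tif"))),
    )


def npp_stage(cfg: PipelineConfig, workspace: str) -> str:
    """Calibrate class bounds from the NDVI history and run CASA."""
    ndvi = raster_io.read_raster_stack(_require(os.path.join(workspace, "ndvi.tif")))
    landcover, lc_grid, _ = raster_io.read_raster(
        _require(os.path.join(workspace, "world", "landcover.tif")))
    ndvi.grid.require_same(lc_grid)
    climate = _read_climate(workspace)
    landcover = np.nan_to_num(landcover, nan=-1).astype(int)
    eps_by_class = {CLASS_IDS[name]: value for name, value in cfg.eps_max.items()}
    params = casa_core.calibrate_class_bounds(
        ndvi.data, landcover, eps_by_class,
        pct_lo=cfg.calib_pct_lo, pct_hi=cfg.calib_pct_hi,
        names={v: k for k, v in CLASS_IDS.items()})
    constants = casa_core.FparConstants(cfg.fpar_min, cfg.fpar_max)
    series = casa_core.run_casa(ndvi, climate, landcover, params,
                                constants=constants, latitude=cfg.latitude,
                                bucket_capacity=cfg.bucket_capacity_mm)
    out = os.path.join(workspace, "npp_monthly.tif")
    raster_io.write_raster_stack(series.monthly, out)
    _write_json({str(cid): {"ndvi_min": p.ndvi_min, "ndvi_max": p.ndvi_max,
                            "sr_min": p.sr_min, "sr_max": p.sr_max,
                            "eps_max": p.eps_max, "name": p.name}
                 for cid, p in params.items()},
                os.path.join(workspace, "class_params.json"))
    return out


def aggregate_stage(cfg: PipelineConfig, workspace: str) -> dict:
    """Annual/seasonal rasters, regional series, trend and ACF."""
    npp = raster_io.read_raster_stack(
        _require(os.path.join(workspace, "npp_monthly.tif")))
    climate = _read_climate(workspace)
    annual = aggregation.annual_npp(npp)
    for yi, year in enumerate(npp.years):
        raster_io.write_raster(annual[yi], npp.grid,
                               os.path.join(workspace, f"npp_annual_{year}.tif"),
                               variable="npp_annual", units="gC m-2 yr-1",
                               year=year)
        for season in ("spring", "summer", "autumn"):
            seasonal = aggregation.seasonal_npp(npp, season)
            raster_io.write_raster(
                seasonal[yi], npp.grid,
                os.path.join(workspace, f"npp_{season}_{year}.tif"),
                variable=f"npp_{season}", units="gC m-2 season-1", year=year)

    npp_series = aggregation.regional_mean_series(annual, npp.years, variable="npp")
    precip_series = aggregation.regional_mean_series(
        climate.precipitation.data.sum(axis=1), npp.years, variable="precip")
    temp_series = aggregation.regional_mean_series(
        climate.temperature.data.mean(axis=1), npp.years, variable="temp")
    frame = pd.DataFrame({
        "year": npp.years,
        "npp": npp_series.values, "precip": precip_series.values,
        "temp": temp_series.values,
        "anomaly_npp": npp_series.anomalies,
        "anomaly_precip": precip_series.anomalies,
        "anomaly_temp": temp_series.anomalies,
    })
    _write_csv(frame, os.path.join(workspace, "regional_series.csv"))
    max_lag = min(8, len(npp.years) - 1)
    acf_res = aggregation.acf(npp_series.values, max_lag)
    summary = {
        "trend_npp": aggregation.linear_trend(npp_series),
        "trend_precip": aggregation.linear_trend(precip_series),
        "trend_temp": aggregation.linear_trend(temp_series),
        "acf_npp": {"lags": acf_res["lags"], "acf": list(np.asarray(acf_res["acf"])),
                    "lower": acf_res["lower"], "upper": acf_res["upper"],
                    "n": acf_res["n"]},
        "mean_annual_npp": float(np.nanmean(npp_series.values)),
    }
    _write_json(summary, os.path.join(workspace, "trend_acf.json"))
    return summary


def validate_stage(cfg: PipelineConfig, workspace: str) -> dict:
    """Compare modelled NPP with the clip-plot observations."""
    npp = raster_io.read_raster_stack(
        _require(os.path.join(workspace, "npp_monthly.tif")))
    plots = pd.read_csv(_require(os.path.join(workspace, "world", "plots.csv")))
    year = int(plots["year"].iloc[0]) if "year" in plots else npp.years[-1]
    series = casa_core.NppSeries(monthly=npp)
    table = validation_mod.extract_estimates(
        series, plots, year, through_month=cfg.validation_through_month)
    stats = validation_mod.validation_stats(table)
    _write_csv(table.frame, os.path.join(workspace, "validation_pairs.csv"))
    _write_json(stats, os.path.join(workspace, "validation.json"))
    return stats


def attribute_stage(cfg: PipelineConfig, workspace: str) -> dict:
    """Pixel and county correlation/partial-correlation attribution."""
    npp = raster_io.read_raster_stack(
        _require(os.path.join(workspace, "npp_monthly.tif")))
    climate = _read_climate(workspace)
    counties, cg, _ = raster_io.read_raster(
        _require(os.path.join(workspace, "world", "counties.tif")))
    npp.grid.require_same(cg)
    counties = np.nan_to_num(counties, nan=0).astype(int)
    outdir = os.path.join(workspace, "attribution")
    os.makedirs(outdir, exist_ok=True)

    scopes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    annual_npp = aggregation.annual_npp(npp)
    scopes["annual"] = (annual_npp,
                        climate.precipitation.data.sum(axis=1),
                        climate.temperature.data.mean(axis=1))
    for season in ("spring", "summer", "autumn"):
        scopes[season] = (aggregation.seasonal_npp(npp, season),
                          aggregation.seasonal_sum(climate.precipitation, season),
                          aggregation.seasonal_mean(climate.temperature, season))

    summaries: dict[str, dict] = {}
    for scope, (npp_stack, precip_stack, temp_stack) in scopes.items():
        combos = {
            "precip_r": dict(climate=precip_stack, control=None,
                             target="precipitation"),
            "precip_partial": dict(climate=precip_stack, control=temp_stack,
                                   target="precipitation", controlled="temperature"),
            "temp_r": dict(climate=temp_stack, control=None,
                           target="temperature"),
            "temp_partial": dict(climate=temp_stack, control=precip_stack,
                                 target="temperature", controlled="precipitation"),
        }
        for name, kw in combos.items():
            amap = climate_attribution.correlation_map(
                npp_stack, fdr=cfg.attribution_fdr, **kw)
            raster_io.write_raster(amap.r, npp.grid,
                                   os.path.join(outdir, f"{scope}_{name}.tif"),
                                   variable=f"{scope}_{name}_r")
            raster_io.write_raster(amap.p, npp.grid,
                                   os.path.join(outdir, f"{scope}_{name}_p.tif"),
                                   variable=f"{scope}_{name}_p")
            summaries[f"{scope}_{name}"] = climate_attribution.map_summary(
                amap, alpha=cfg.attribution_alpha, bin_width=cfg.hist_bin_width)
    _write_json(summaries, os.path.join(outdir, "summaries.json"))

    table = climate_attribution.county_table(
        npp.data, climate.precipitation.data, climate.temperature.data,
        counties, npp.years)
    _write_csv(table, os.path.join(outdir, "county_table.csv"))
    return summaries


def run_all(cfg: PipelineConfig, workspace: str, seed: int | None = None) -> dict:
    """Execute the full chain on the synthetic world; returns stage summaries."""
    os.makedirs(workspace, exist_ok=True)
    simulate(cfg, workspace, seed=seed)
    ndvi_stage(cfg, workspace)
    interpolate_stage(cfg, workspace)
    npp_stage(cfg, workspace)
    agg = aggregate_stage(cfg, workspace)
    val = validate_stage(cfg, workspace)
    attr = attribute_stage(cfg, workspace)
    return {"aggregate": agg, "validation": val, "attribution": attr}
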