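"""Gridded and tabular I/O on one shared raster grid.

Rasters are exchanged as GeoTIFF-compatible TIFF files carrying the
geotransform in the standard ModelPixelScale / ModelTiepoint tags and the
nodata sentinel in the GDAL_NODATA tag, written via :mod:`tifffile`.
Monthly time series travel as multi-page files, one page per (year, month)
layer, each page tagged with its date in the image description.

Internally every raster is a float array with ``NaN`` marking nodata, so
nodata pixels never enter an aggregate; the sentinel value only appears on
disk.

Conventions: pixel centres; row 0 is the northern edge; x increases
eastward; all indexing is 0-based.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, DataValidationError, GridMismatchError, MissingInputError

__all__ = [
    "RasterGrid",
    "MonthlyStack",
    "StationRecord",
    "read_raster",
    "write_raster",
    "read_raster_stack",
    "write_raster_stack",
    "read_stations",
    "write_stations",
    "stations_to_frame",
]

STATION_COLUMNS = ["station_id", "x", "y", "year", "month", "temp_c", "precip_mm", "sunshine_h"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class RasterGrid:
    """Common pixel grid shared by every gridded product.

    ``origin_x``/``origin_y`` locate the outer corner of the top-left
    (north-west) pixel in map units.
    """

    rows: int
    cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 500.0
    crs_id: str = "local"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ConfigError(f"grid shape must be positive, got {self.rows}x{self.cols}")
        if self.pixel_size <= 0:
            raise ConfigError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every pixel centre, each (rows, cols)."""
        xs = self.origin_x + (np.arange(self.cols) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(self.rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the pixel containing map point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((self.origin_y - y) / self.pixel_size))
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise DataValidationError(
                f"point ({x}, {y}) falls outside the {self.rows}x{self.cols} grid"
            )
        return row, col

    def contains(self, x: float, y: float) -> bool:
        try:
            self.index_of(x, y)
        except DataValidationError:
            return False
        return True

    def require_same(self, other: "RasterGrid") -> None:
        if (self.rows, self.cols, self.origin_x, self.origin_y, self.pixel_size, self.crs_id) != (
            other.rows, other.cols, other.origin_x, other.origin_y, other.pixel_size, other.crs_id
        ):
            raise GridMismatchError(f"grids differ: {self} vs {other}")


@dataclass
class MonthlyStack:
    """Per-pixel monthly values, indexed (year, month, row, col).

    ``data`` has shape (n_years, 12, rows, cols) with NaN for nodata.
    Missing months are simply all-NaN layers; readers flag gaps explicitly.
    """

    grid: RasterGrid
    years: list[int]
    data: np.ndarray
    variable: str = "value"
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (len(self.years), 12, self.grid.rows, self.grid.cols)
        if self.data.shape != expected:
            raise ConfigError(
                f"stack shape {self.data.shape} does not match (years, 12, rows, cols)={expected}"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    def layer(self, year: int, month: int) -> np.ndarray:
        if month < 1 or month > 12:
            raise ConfigError(f"month must be in 1..12, got {month}")
        return self.data[self.years.index(year), month - 1]

    def copy_like(self, data: np.ndarray, variable: str | None = None, units: str | None = None) -> "MonthlyStack":
        return MonthlyStack(
            grid=self.grid,
            years=list(self.years),
            data=data,
            variable=variable if variable is not None else self.variable,
            units=units if units is not None else self.units,
        )


@dataclass(frozen=True)
class StationRecord:
    """One station-month meteorological record."""

    station_id: str
    x: float
    y: float
    year: int
    month: int
    temp_c: float
    precip_mm: float
    sunshine_h: float

    def __post_init__(self) -> None:
        if self.precip_mm < 0:
            raise DataValidationError(
                f"station {self.station_id} {self.year}-{self.month:02d}: negative precipitation"
            )
        if not (0 <= self.sunshine_h <= 744):
            raise DataValidationError(
                f"station {self.station_id} {self.year}-{self.month:02d}: "
                f"sunshine hours {self.sunshine_h} outside [0, 744]"
            )
        if not (1 <= self.month <= 12):
            raise DataValidationError(f"month {self.month} outside 1..12")


# ---------------------------------------------------------------------------
# GeoTIFF helpers

def _geo_extratags(grid: RasterGrid) -> list[tuple]:
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.pixel_size), float(grid.pixel_size), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata), True),
    ]


def _grid_from_page(page: tifffile.TiffPage, path: str) -> RasterGrid:
    try:
        sx, sy, _ = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
        nodata = float(page.tags[_TAG_GDAL_NODATA].value)
    except KeyError as exc:
        raise DataValidationError(f"{path}: missing geo tags ({exc})") from exc
    meta = _page_meta(page)
    return RasterGrid(
        rows=page.imagelength,
        cols=page.imagewidth,
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        pixel_size=float(sx),
        crs_id=meta.get("crs_id", "local"),
        nodata=nodata,
    )


def _page_meta(page: tifffile.TiffPage) -> dict:
    desc = page.description
    if not desc:
        return {}
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        return {}
    return meta if isinstance(meta, dict) else {}


def _mask_in(arr: np.ndarray, nodata: float) -> np.ndarray:
    out = np.asarray(arr, dtype=np.float64).copy()
    out[out == nodata] = np.nan
    return out


def _mask_out(arr: np.ndarray, nodata: float) -> np.ndarray:
    out = np.asarray(arr, dtype=np.float32).copy()
    out[np.isnan(out)] = nodata
    return out


def _atomic_path(path: str) -> str:
    return path + ".part"


def write_raster(array: np.ndarray, grid: RasterGrid, path: str | os.PathLike,
                 variable: str = "value", units: str = "", **meta) -> None:
    """Write one 2-D band as a single-page GeoTIFF; NaN stored as nodata."""
    path = os.fspath(path)
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise GridMismatchError(f"array shape {array.shape} does not match grid {grid.shape}")
    desc = json.dumps({"crs_id": grid.crs_id, "variable": variable, "units": units, **meta},
                      sort_keys=True)
    tmp = _atomic_path(path)
    tifffile.imwrite(tmp, _mask_out(array, grid.nodata),
                     extratags=_geo_extratags(grid), description=desc)
    os.replace(tmp, path)


def read_raster(path: str | os.PathLike) -> tuple[np.ndarray, RasterGrid, dict]:
    """Read a single-band GeoTIFF -> (values with NaN nodata, grid, metadata)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MissingInputError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        grid = _grid_from_page(page, path)
        meta = _page_meta(page)
        return _mask_in(page.asarray(), grid.nodata), grid, meta


def write_raster_stack(stack: MonthlyStack, path: str | os.PathLike) -> None:
    """Write a MonthlyStack as a multi-page GeoTIFF, one page per year-month."""
    path = os.fspath(path)
    tags = _geo_extratags(stack.grid)
    tmp = _atomic_path(path)
    with tifffile.TiffWriter(tmp) as tw:
        for yi, year in enumerate(stack.years):
            for month in range(1, 13):
                desc = json.dumps(
                    {"crs_id": stack.grid.crs_id, "variable": stack.variable,
                     "units": stack.units, "year": int(year), "month": month},
                    sort_keys=True)
                tw.write(_mask_out(stack.data[yi, month - 1], stack.grid.nodata),
                         extratags=tags, description=desc, contiguous=False)
    os.replace(tmp, path)


def read_raster_stack(paths: str | os.PathLike | Sequence[str | os.PathLike]) -> MonthlyStack:
    """Read a monthly stack from one multi-page file or many single-band files.

    Every page must carry ``year`` and ``month`` metadata. Layers must share
    one grid (hard error naming both grids otherwise) and cover each listed
    year completely (missing months are a hard error listing the gaps).
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    layers: dict[tuple[int, int], np.ndarray] = {}
    grid: RasterGrid | None = None
    variable, units = "value", ""
    for path in paths:
        path = os.fspath(path)
        if not os.path.exists(path):
            raise MissingInputError(f"raster not found: {path}")
        with tifffile.TiffFile(path) as tf:
            for page in tf.pages:
                pg_grid = _grid_from_page(page, path)
                if grid is None:
                    grid = pg_grid
                else:
                    try:
                        grid.require_same(pg_grid)
                    except GridMismatchError as exc:
                        raise GridMismatchError(f"{path}: {exc}") from exc
                meta = _page_meta(page)
                if "year" not in meta or "month" not in meta:
                    raise DataValidationError(f"{path}: page lacks year/month metadata")
                variable = meta.get("variable", variable)
                units = meta.get("units", units)
                layers[(int(meta["year"]), int(meta["month"]))] = _mask_in(
                    page.asarray(), pg_grid.nodata)
    if grid is None or not layers:
        raise MissingInputError("no raster layers found")
    years = sorted({y for y, _ in layers})
    gaps = [(y, m) for y in years for m in range(1, 13) if (y, m) not in layers]
    if gaps:
        raise MissingInputError(
            "missing months: " + ", ".join(f"{y}-{m:02d}" for y, m in gaps))
    data = np.stack([
        np.stack([layers[(y, m)] for m in range(1, 13)]) for y in years
    ])
    return MonthlyStack(grid=grid, years=years, data=data, variable=variable, units=units)


# ---------------------------------------------------------------------------
# Station tables

def write_stations(records: Iterable[StationRecord] | pd.DataFrame, path: str | os.PathLike) -> None:
    frame = records if isinstance(records, pd.DataFrame) else stations_to_frame(list(records))
    tmp = _atomic_path(os.fspath(path))
    frame.to_csv(tmp, index=False)
    os.replace(tmp, os.fspath(path))


def stations_to_frame(records: Sequence[StationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=STATION_COLUMNS)


def read_stations(path: str | os.PathLike) -> list[StationRecord]:
    """Read and validate the station CSV (schema in module docstring)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MissingInputError(f"station file not found: {path}")
    frame = pd.read_csv(path)
    missing = set(STATION_COLUMNS) - set(frame.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(StationRecord(
            station_id=str(row.station_id), x=float(row.x), y=float(row.y),
            year=int(row.year), month=int(row.month), temp_c=float(row.temp_c),
            precip_mm=float(row.precip_mm), sunshine_h=float(row.sunshine_h)))
    return records
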