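"""Daily Tmin/Tmax temperature grids: containers, I/O, synthesis.

Grids are north-up lat/lon rasters (row 0 = northernmost) holding one
calendar year (or a consecutive run of days) of daily minimum and
maximum temperature.  Missing data is ``NaN`` internally and a sentinel
on disk.  Files are GeoTIFF: one multiband file per variable per year
(band = day), or one single-band file per variable per day, written and
read through :mod:`tifffile` with geolocation tags (pixel scale, tie
point, EPSG:4326 geokeys) plus a JSON description carrying dates and
the nodata sentinel.

A synthetic generator produces seasonally varying grids with a
latitudinal gradient so every downstream computation is testable
without external climate downloads.
"""

from __future__ import annotations

import glob
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import tifffile
from numpy.typing import NDArray

from .params import parse_flat_config

__all__ = [
    "DailyClimateGrid",
    "SyntheticClimateSpec",
    "read_climate",
    "write_climate",
    "aggregate_resolution",
    "weekly_extreme",
    "generate_synthetic_climate",
    "read_synthetic_spec",
]

log = logging.getLogger(__name__)

NODATA = -9999.0

# GeoTIFF tags: pixel scale, tie point, and a minimal geokey directory
# declaring a geographic WGS84 (EPSG:4326) raster.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_GEOKEYS_4326 = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass
class DailyClimateGrid:
    """Georeferenced daily Tmin/Tmax stacks, ``[day, row, col]``.

    ``bounds`` is ``(west, south, east, north)`` in degrees; rows run
    north to south.  ``NaN`` marks missing cells; ``tmax >= tmin``
    wherever both are valid.
    """

    tmin: NDArray[np.floating]
    tmax: NDArray[np.floating]
    dates: list[date]
    bounds: tuple[float, float, float, float]
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.tmin = np.asarray(self.tmin, dtype=np.float64)
        self.tmax = np.asarray(self.tmax, dtype=np.float64)
        if self.tmin.shape != self.tmax.shape:
            raise ValueError(
                f"tmin shape {self.tmin.shape} != tmax shape {self.tmax.shape}"
            )
        if self.tmin.ndim != 3:
            raise ValueError("expected [day, row, col] arrays")
        if len(self.dates) != self.tmin.shape[0]:
            raise ValueError(
                f"{len(self.dates)} dates for {self.tmin.shape[0]} layers"
            )
        for prev, cur in zip(self.dates, self.dates[1:]):
            if (cur - prev).days != 1:
                raise ValueError(f"dates not consecutive: gap after {prev}")
        west, south, east, north = self.bounds
        if not (east > west and north > south):
            raise ValueError(f"invalid bounds {self.bounds}")
        both = ~np.isnan(self.tmin) & ~np.isnan(self.tmax)
        bad = both & (self.tmax < self.tmin)
        if bad.any():
            n = int(bad.sum())
            log.warning("masking %d cells with tmax < tmin", n)
            self.tmin[bad] = np.nan
            self.tmax[bad] = np.nan

    # -- geometry --------------------------------------------------------

    @property
    def n_days(self) -> int:
        return self.tmin.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmin.shape[1:]

    @property
    def resolution(self) -> tuple[float, float]:
        """(lon, lat) cell size in degrees."""
        west, south, east, north = self.bounds
        nrow, ncol = self.shape
        return (east - west) / ncol, (north - south) / nrow

    @property
    def lats(self) -> NDArray[np.float64]:
        """Cell-centre latitudes by row, north to south."""
        _, south, _, north = self.bounds
        _, dy = self.resolution
        return north - dy * (np.arange(self.shape[0]) + 0.5)

    @property
    def lons(self) -> NDArray[np.float64]:
        west, _, _, _ = self.bounds
        dx, _ = self.resolution
        return west + dx * (np.arange(self.shape[1]) + 0.5)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing (or nearest to) a coordinate.

        Raises ``ValueError`` for coordinates outside the extent.
        """
        west, south, east, north = self.bounds
        if not (west <= lon <= east and south <= lat <= north):
            raise ValueError(
                f"({lon}, {lat}) outside extent {self.bounds}"
            )
        dx, dy = self.resolution
        col = min(int((lon - west) / dx), self.shape[1] - 1)
        row = min(int((north - lat) / dy), self.shape[0] - 1)
        return row, col

    def valid_mask(self) -> NDArray[np.bool_]:
        """Cells with a complete (no missing day) Tmin/Tmax series."""
        return ~(np.isnan(self.tmin).any(axis=0) | np.isnan(self.tmax).any(axis=0))

    def require_full_year(self) -> int:
        """Check the grid spans one calendar year; return the year."""
        first, last = self.dates[0], self.dates[-1]
        if first != date(first.year, 1, 1) or last != date(first.year, 12, 31):
            raise ValueError(
                f"full calendar year required, got {first}..{last}"
            )
        return first.year


# -- I/O -----------------------------------------------------------------


def _geo_tags(grid_bounds, shape):
    west, south, east, north = grid_bounds
    nrow, ncol = shape
    dx = (east - west) / ncol
    dy = (north - south) / nrow
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (dx, dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),
        (_TAG_GEOKEYS, "H", len(_GEOKEYS_4326), _GEOKEYS_4326),
    ]


def _write_tif(path, data, description, bounds) -> None:
    tifffile.imwrite(
        path,
        np.asarray(data, dtype=np.float32),
        description=json.dumps(description),
        extratags=_geo_tags(bounds, data.shape[-2:]),
        photometric="minisblack",
    )


def write_raster(
    path: str | Path,
    data: NDArray,
    bounds: tuple[float, float, float, float],
    nodata: float = NODATA,
    meta: dict | None = None,
) -> None:
    """Write a single 2-D raster as a geolocated float32 TIFF."""
    arr = np.asarray(data, dtype=np.float32).copy()
    arr[np.isnan(arr)] = nodata
    desc = {"nodata": nodata, "bounds": list(bounds), "crs": "EPSG:4326"}
    if meta:
        desc.update(meta)
    _write_tif(str(path), arr, desc, bounds)


def read_raster(path: str | Path) -> tuple[NDArray[np.float64], dict]:
    """Read a raster written by :func:`write_raster`; nodata becomes NaN."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray().astype(np.float64)
        desc = json.loads(tif.pages[0].tags["ImageDescription"].value)
    arr[arr == desc["nodata"]] = np.nan
    return arr, desc


def write_climate(
    grid: DailyClimateGrid,
    directory: str | Path,
    pattern: str = "{var}_{year}.tif",
) -> list[Path]:
    """Write a grid to GeoTIFFs under ``directory``.

    With ``{date}`` in the pattern, one single-band file per variable
    per day; otherwise one multiband (band = day) file per variable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    year = grid.dates[0].year
    written: list[Path] = []
    for var in ("tmin", "tmax"):
        stack = getattr(grid, var).astype(np.float32).copy()
        stack[np.isnan(stack)] = NODATA
        desc = {
            "nodata": NODATA,
            "bounds": list(grid.bounds),
            "crs": grid.crs,
            "var": var,
        }
        if "{date}" in pattern:
            for i, d in enumerate(grid.dates):
                path = directory / pattern.format(var=var, year=year, date=d.isoformat())
                _write_tif(str(path), stack[i], {**desc, "dates": [d.isoformat()]}, grid.bounds)
                written.append(path)
        else:
            path = directory / pattern.format(var=var, year=year)
            desc["dates"] = [d.isoformat() for d in grid.dates]
            _write_tif(str(path), stack, desc, grid.bounds)
            written.append(path)
    return written


def _read_stack(paths: list[Path]) -> tuple[NDArray, list[date], dict]:
    layers, dates, desc = [], [], {}
    for path in paths:
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray().astype(np.float64)
            desc = json.loads(tif.pages[0].tags["ImageDescription"].value)
        arr[arr == desc["nodata"]] = np.nan
        if arr.ndim == 2:
            arr = arr[None]
        layers.append(arr)
        dates.extend(date.fromisoformat(s) for s in desc["dates"])
    order = np.argsort(np.array(dates, dtype="datetime64[D]"))
    stack = np.concatenate(layers, axis=0)[order]
    dates = [dates[i] for i in order]
    return stack, dates, desc


def read_climate(path_pattern: str | Path, year: int) -> DailyClimateGrid:
    """Read a year of daily Tmin/Tmax GeoTIFFs.

    ``path_pattern`` is a directory (default layout ``{var}_{year}.tif``)
    or a pattern with ``{var}``/``{year}``/``{date}`` placeholders.
    Missing dates raise an error naming the gap; cells with
    ``tmax < tmin`` are masked with a logged count.
    """
    pattern = str(path_pattern)
    if Path(pattern).is_dir():
        pattern = str(Path(pattern) / "{var}_{year}.tif")
    stacks: dict[str, NDArray] = {}
    var_dates: dict[str, list[date]] = {}
    desc: dict = {}
    for var in ("tmin", "tmax"):
        glob_pat = pattern.format(var=var, year=year, date="*")
        paths = sorted(glob.glob(glob_pat))
        if not paths:
            raise FileNotFoundError(f"no {var} files matching {glob_pat}")
        stacks[var], var_dates[var], desc = _read_stack([Path(p) for p in paths])
    if var_dates["tmin"] != var_dates["tmax"]:
        tmin_set, tmax_set = set(var_dates["tmin"]), set(var_dates["tmax"])
        for var, missing in (("tmin", tmax_set - tmin_set), ("tmax", tmin_set - tmax_set)):
            if missing:
                raise ValueError(
                    f"{var} layer missing for {sorted(missing)[0].isoformat()}"
                )
    dates = var_dates["tmin"]
    for prev, cur in zip(dates, dates[1:]):
        if (cur - prev).days != 1:
            raise ValueError(
                f"missing dates between {prev.isoformat()} and {cur.isoformat()}"
            )
    if stacks["tmin"].shape != stacks["tmax"].shape:
        raise ValueError(
            f"shape mismatch: tmin {stacks['tmin'].shape}, tmax {stacks['tmax'].shape}"
        )
    return DailyClimateGrid(
        tmin=stacks["tmin"],
        tmax=stacks["tmax"],
        dates=dates,
        bounds=tuple(desc["bounds"]),
        crs=desc.get("crs", "EPSG:4326"),
    )


# -- resampling and weekly extremes --------------------------------------


def aggregate_resolution(grid: DailyClimateGrid, factor: int) -> DailyClimateGrid:
    """Block-mean aggregation by an integer factor.

    Each ``factor x factor`` block is averaged over its valid cells;
    a block that is entirely missing stays missing.  The extent is
    padded east/south to a whole number of blocks.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return grid
    nrow, ncol = grid.shape
    if factor > min(nrow, ncol):
        raise ValueError(f"factor {factor} exceeds grid dimension {min(nrow, ncol)}")
    dx, dy = grid.resolution
    pad_r = (-nrow) % factor
    pad_c = (-ncol) % factor

    def block_mean(stack: NDArray) -> NDArray:
        padded = np.pad(
            stack, ((0, 0), (0, pad_r), (0, pad_c)), constant_values=np.nan
        )
        d, r, c = padded.shape
        blocks = padded.reshape(d, r // factor, factor, c // factor, factor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
            return np.nanmean(blocks, axis=(2, 4))

    west, south, east, north = grid.bounds
    new_bounds = (west, south - pad_r * dy, east + pad_c * dx, north)
    return DailyClimateGrid(
        tmin=block_mean(grid.tmin),
        tmax=block_mean(grid.tmax),
        dates=list(grid.dates),
        bounds=new_bounds,
        crs=grid.crs,
    )


def weekly_extreme(grid: DailyClimateGrid, which: str) -> NDArray[np.float64]:
    """Extreme 7-day-mean temperature per cell over the year.

    ``which="coldest_week_tmin"``: minimum over all rolling 7-day
    windows of the window-mean Tmin.  ``which="hottest_week_tmax"``:
    maximum of the 7-day-mean Tmax.  Rolling windows at every alignment
    are used, so the coldest (hottest) week bounds any calendar-week
    value.  Cells missing any day are NaN.
    """
    if which == "coldest_week_tmin":
        stack, reduce = grid.tmin, np.min
    elif which == "hottest_week_tmax":
        stack, reduce = grid.tmax, np.max
    else:
        raise ValueError(f"unknown extreme {which!r}")
    if grid.n_days < 7:
        raise ValueError(f"need >= 7 days, got {grid.n_days}")
    windows = np.lib.stride_tricks.sliding_window_view(stack, 7, axis=0)
    return reduce(windows.mean(axis=-1), axis=0)


# -- synthetic climate ---------------------------------------------------


@dataclass
class SyntheticClimateSpec:
    """Recipe for a synthetic daily-temperature grid.

    Daily mean temperature at a cell is
    ``base - lapse * (lat - lat_ref) + amplitude * cos(2 pi (doy - peak_doy) / 365)``
    plus Gaussian noise; Tmin/Tmax sit half the diurnal range below and
    above the mean.  ``lat_ref`` defaults to the southern edge, so
    ``base`` is the annual mean on the warm edge of the grid.
    """

    n_rows: int = 20
    n_cols: int = 20
    lat_min: float = 30.0
    lat_max: float = 50.0
    lon_min: float = -100.0
    lon_max: float = -80.0
    base_temp: float = 18.0
    lapse_per_degree: float = 0.8
    seasonal_amplitude: float = 12.0
    diurnal_range: float = 10.0
    noise_sd: float = 1.5
    peak_doy: int = 196
    lat_ref: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diurnal_range < 0:
            raise ValueError("diurnal range must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("empty extent")
        if self.lat_ref is None:
            self.lat_ref = self.lat_min


def generate_synthetic_climate(
    spec: SyntheticClimateSpec, year: int
) -> DailyClimateGrid:
    """Generate a deterministic (seeded) synthetic year of Tmin/Tmax."""
    start = date(year, 1, 1)
    n_days = (date(year, 12, 31) - start).days + 1
    dates = [start + timedelta(days=i) for i in range(n_days)]
    doy = np.arange(1, n_days + 1, dtype=np.float64)

    bounds = (spec.lon_min, spec.lat_min, spec.lon_max, spec.lat_max)
    dy = (spec.lat_max - spec.lat_min) / spec.n_rows
    lats = spec.lat_max - dy * (np.arange(spec.n_rows) + 0.5)

    seasonal = spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - spec.peak_doy) / 365.0
    )
    tmean = (
        spec.base_temp
        - spec.lapse_per_degree * (lats - spec.lat_ref)[None, :, None]
        + seasonal[:, None, None]
        + np.zeros((n_days, spec.n_rows, spec.n_cols))
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        tmean = tmean + rng.normal(0.0, spec.noise_sd, size=tmean.shape)
    half = spec.diurnal_range / 2.0
    return DailyClimateGrid(
        tmin=tmean - half, tmax=tmean + half, dates=dates, bounds=bounds
    )


_SPEC_FIELDS = {
    "n_rows": int, "n_cols": int, "peak_doy": int, "seed": int,
    "lat_min": float, "lat_max": float, "lon_min": float, "lon_max": float,
    "base_temp": float, "lapse_per_degree": float, "seasonal_amplitude": float,
    "diurnal_range": float, "noise_sd": float, "lat_ref": float,
}


def read_synthetic_spec(path: str | Path) -> SyntheticClimateSpec:
    """Read a flat ``key = value`` synthetic-climate spec file."""
    raw = parse_flat_config(Path(path).read_text().splitlines())
    kwargs = {}
    for key, val in raw.items():
        if key not in _SPEC_FIELDS:
            raise ValueError(f"unknown synthetic-climate key {key!r}")
        kwargs[key] = _SPEC_FIELDS[key](val)
    return SyntheticClimateSpec(**kwargs)
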