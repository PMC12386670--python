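"""End-to-end runs: climate -> phenology + stress -> maps -> manifest.

A run is described by a flat ``key = value`` config file naming the
climate source (GeoTIFF directory/pattern, or a synthetic-climate spec
file), the years to model, the species parameter file, and the output
directory.  Each modelled year produces the five phenological event
maps (earliest-cohort and cohort-weighted mean, GeoTIFF + PNG), annual
cold/heat stress rasters, and the exclusion map; across years the
potential-distribution year-count map is written.  A JSON manifest
lists every product with a checksum so runs can be audited and
compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import climate as clim
from .params import SpeciesParams, parse_flat_config, read_params_file
from .phenology import EVENTS, build_cohorts, run_annual_cycle
from .render import render_map
from .suitability import accumulate_stress, classify_exclusion, combine_years

__all__ = ["RunConfig", "read_run_config", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one multi-year model run."""

    years: list[int]
    output_dir: Path
    climate_source: str | None = None  # directory or {var}/{year} pattern
    synthetic_spec: Path | None = None
    params_file: Path | None = None
    crop: tuple[float, float, float, float] | None = None
    aggregate_mode: str = "earliest"
    aggregate_factor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("at least one year is required")
        if self.climate_source is None and self.synthetic_spec is None:
            raise ValueError("config needs climate_source or synthetic_spec")
        if self.aggregate_mode not in {"earliest", "weighted_mean"}:
            raise ValueError(f"unknown aggregate mode {self.aggregate_mode!r}")


def read_run_config(path: str | Path) -> RunConfig:
    raw = parse_flat_config(Path(path).read_text().splitlines())
    kwargs: dict[str, object] = {}
    for key, val in raw.items():
        if key == "years":
            kwargs["years"] = [int(y) for y in val.split(",")]
        elif key == "output_dir":
            kwargs["output_dir"] = Path(val)
        elif key == "climate_source":
            kwargs["climate_source"] = val
        elif key == "synthetic_spec":
            kwargs["synthetic_spec"] = Path(val)
        elif key == "params_file":
            kwargs["params_file"] = Path(val)
        elif key == "crop":
            kwargs["crop"] = tuple(float(x) for x in val.split(","))
        elif key == "aggregate_mode":
            kwargs["aggregate_mode"] = val
        elif key == "aggregate_factor":
            kwargs["aggregate_factor"] = int(val)
        elif key == "seed":
            kwargs["seed"] = int(val)
        else:
            raise ValueError(f"unknown run-config key {key!r}")
    return RunConfig(**kwargs)


def _crop_grid(grid: clim.DailyClimateGrid, box) -> clim.DailyClimateGrid:
    west, south, east, north = box
    dx, dy = grid.resolution
    gw, gs, ge, gn = grid.bounds
    c0 = max(int(np.floor((west - gw) / dx)), 0)
    c1 = min(int(np.ceil((east - gw) / dx)), grid.shape[1])
    r0 = max(int(np.floor((gn - north) / dy)), 0)
    r1 = min(int(np.ceil((gn - south) / dy)), grid.shape[0])
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"crop box {box} does not intersect extent {grid.bounds}")
    return clim.DailyClimateGrid(
        tmin=grid.tmin[:, r0:r1, c0:c1],
        tmax=grid.tmax[:, r0:r1, c0:c1],
        dates=list(grid.dates),
        bounds=(gw + c0 * dx, gn - r1 * dy, gw + c1 * dx, gn - r0 * dy),
        crs=grid.crs,
    )


def _load_year(config: RunConfig, year: int, index: int) -> clim.DailyClimateGrid:
    if config.synthetic_spec is not None:
        spec = clim.read_synthetic_spec(config.synthetic_spec)
        # distinct but reproducible weather per modelled year
        spec.seed = config.seed + index
        grid = clim.generate_synthetic_climate(spec, year)
    else:
        grid = clim.read_climate(config.climate_source, year)
    if config.crop is not None:
        grid = _crop_grid(grid, config.crop)
    if config.aggregate_factor > 1:
        grid = clim.aggregate_resolution(grid, config.aggregate_factor)
    return grid


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full model for every configured year.

    Returns the manifest (also written to ``manifest.json``): per-year
    product paths with SHA-256 checksums, the parameter provenance,
    and per-year valid/excluded cell counts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = (
        read_params_file(config.params_file)
        if config.params_file
        else SpeciesParams()
    )
    cohorts = build_cohorts(params)
    manifest: dict = {
        "params_file": str(config.params_file) if config.params_file else "defaults",
        "seed": config.seed,
        "years": {},
        "files": {},
    }

    def emit(path: Path, raster, bounds, style: str, title: str) -> None:
        clim.write_raster(path, raster, bounds)
        png = path.with_suffix(".png")
        render_map(raster, style, png, bounds=bounds, title=title)
        for p in (path, png):
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    exclusions = []
    for index, year in enumerate(config.years):
        stage = f"climate {year}"
        try:
            grid = _load_year(config, year, index)
            n_valid = int(grid.valid_mask().sum())
            log.info("%s: %d valid cells of %d", stage, n_valid, grid.shape[0] * grid.shape[1])

            stage = f"phenology {year}"
            _, maps = run_annual_cycle(grid, params, cohorts, keep_trajectory=False)
            ydir = out / str(year)
            ydir.mkdir(exist_ok=True)
            for event in EVENTS:
                for mode in ("earliest", "weighted_mean"):
                    raster = getattr(maps, mode)(event)
                    emit(
                        ydir / f"{event}_{mode}.tif",
                        raster,
                        grid.bounds,
                        "event_doy",
                        f"{event} ({mode}) {year}",
                    )

            stage = f"suitability {year}"
            cold, heat = accumulate_stress(grid, params.stress)
            excl = classify_exclusion(cold, heat, params.stress, bounds=grid.bounds, year=year)
            exclusions.append(excl)
            emit(ydir / "cold_stress_units.tif", cold, grid.bounds, "stress",
                 f"cold stress {year}")
            emit(ydir / "heat_stress_units.tif", heat, grid.bounds, "stress",
                 f"heat stress {year}")
            emit(ydir / "exclusion.tif", excl.combined.astype(float), grid.bounds,
                 "exclusion", f"exclusion {year}")
            manifest["years"][str(year)] = {
                "valid_cells": n_valid,
                "excluded_cells": int((excl.combined > 0).sum()),
            }
        except Exception as err:
            raise RuntimeError(f"pipeline stage failed: {stage}: {err}") from err

    try:
        counts = combine_years(exclusions)
        emit(out / "potential_distribution_years.tif", counts,
             exclusions[0].bounds, "year_count", "years in potential distribution")
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: combine years: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
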