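"""Climatic-suitability mapping from cold/heat stress accumulation.

Stress units (degC-days beyond a cold or heat stress threshold)
accumulate over the calendar year with no recovery.  Annual totals are
classified against two limits per stress: beyond ``max1`` most
individuals die (moderate exclusion, long-term establishment
inhibited), beyond ``max2`` all die (severe exclusion).  Cells not
excluded by either stress form the year's potential distribution;
counting inclusion across years expresses how consistently a location
is climatically suitable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .climate import DailyClimateGrid
from .degree_days import stress_units
from .params import StressParams

__all__ = [
    "ExclusionMap",
    "accumulate_stress",
    "classify_exclusion",
    "combine_years",
    "evaluate_presence_inclusion",
    "CATEGORY_NONE",
    "CATEGORY_MODERATE",
    "CATEGORY_SEVERE",
]

CATEGORY_NONE = 0
CATEGORY_MODERATE = 1
CATEGORY_SEVERE = 2
CATEGORY_NODATA = -1


@dataclass
class ExclusionMap:
    """Per-cell stress-exclusion categories and annual stress units.

    Categories: 0 none, 1 moderate, 2 severe, -1 missing climate.
    ``combined`` is the worse of the cold and heat categories.
    """

    cold_units: NDArray[np.float64]
    heat_units: NDArray[np.float64]
    cold_category: NDArray[np.int8]
    heat_category: NDArray[np.int8]
    bounds: tuple[float, float, float, float]
    year: int | None = None

    @property
    def combined(self) -> NDArray[np.int8]:
        out = np.maximum(self.cold_category, self.heat_category)
        nodata = (self.cold_category == CATEGORY_NODATA) | (
            self.heat_category == CATEGORY_NODATA
        )
        out = out.copy()
        out[nodata] = CATEGORY_NODATA
        return out

    @property
    def included(self) -> NDArray[np.bool_]:
        """Cells in the year's potential distribution (no exclusion)."""
        return self.combined == CATEGORY_NONE


def accumulate_stress(
    grid: DailyClimateGrid, params: StressParams
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Annual cold and heat stress-unit rasters.

    Per cell, the sum over the year of daily triangle-method stress
    units below the cold threshold and above the heat threshold.
    Cells with any missing day are NaN.
    """
    grid.require_full_year()
    cold_daily = np.asarray(
        stress_units(grid.tmin, grid.tmax, params.coldstress_threshold, "cold")
    )
    heat_daily = np.asarray(
        stress_units(grid.tmin, grid.tmax, params.heatstress_threshold, "heat")
    )
    # any missing day invalidates the cell's annual total
    cold = cold_daily.sum(axis=0)
    heat = heat_daily.sum(axis=0)
    invalid = ~grid.valid_mask()
    cold[invalid] = np.nan
    heat[invalid] = np.nan
    return cold, heat


def _classify(units: NDArray, max1: float, max2: float) -> NDArray[np.int8]:
    cat = np.full(units.shape, CATEGORY_NODATA, dtype=np.int8)
    ok = ~np.isnan(units)
    cat[ok & (units <= max1)] = CATEGORY_NONE
    cat[ok & (units > max1) & (units <= max2)] = CATEGORY_MODERATE
    cat[ok & (units > max2)] = CATEGORY_SEVERE
    return cat


def classify_exclusion(
    cold_units: NDArray,
    heat_units: NDArray,
    params: StressParams,
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0),
    year: int | None = None,
) -> ExclusionMap:
    """Classify annual stress units into exclusion categories.

    Units strictly greater than a limit trigger the category: none for
    units <= max1, moderate for max1 < units <= max2, severe above
    max2.  NaN units map to the nodata category.
    """
    cold_units = np.asarray(cold_units, dtype=np.float64)
    heat_units = np.asarray(heat_units, dtype=np.float64)
    for name, units in (("cold", cold_units), ("heat", heat_units)):
        if np.nanmin(units, initial=0.0) < 0:
            raise ValueError(f"negative {name} stress units")
    return ExclusionMap(
        cold_units=cold_units,
        heat_units=heat_units,
        cold_category=_classify(
            cold_units, params.coldstress_units_max1, params.coldstress_units_max2
        ),
        heat_category=_classify(
            heat_units, params.heatstress_units_max1, params.heatstress_units_max2
        ),
        bounds=bounds,
        year=year,
    )


def combine_years(maps: list[ExclusionMap]) -> NDArray[np.float64]:
    """Count, per cell, the years a cell is in the potential distribution.

    A year counts when the combined exclusion category is "none".
    Cells with missing climate in every year are NaN.
    """
    if not maps:
        raise ValueError("at least one exclusion map is required")
    shape = maps[0].cold_units.shape
    bounds = maps[0].bounds
    for m in maps[1:]:
        if m.cold_units.shape != shape or m.bounds != bounds:
            raise ValueError("exclusion maps must share extent and shape")
    counts = np.zeros(shape, dtype=np.float64)
    any_valid = np.zeros(shape, dtype=bool)
    for m in maps:
        combined = m.combined
        counts += combined == CATEGORY_NONE
        any_valid |= combined != CATEGORY_NODATA
    counts[~any_valid] = np.nan
    return counts


def evaluate_presence_inclusion(
    maps: list[ExclusionMap],
    records: pd.DataFrame,
    bounds: tuple[float, float, float, float],
    shape: tuple[int, int],
) -> pd.DataFrame:
    """Fraction of presence records falling in non-excluded cells.

    ``records`` needs ``lon``/``lat`` columns.  Records outside the
    extent or on nodata cells are reported in the returned table but
    excluded from the denominators.  One row per year plus a pooled
    ``overall`` row with columns ``n_used``, ``n_outside``,
    ``n_nodata``, ``included_fraction``.
    """
    if not maps:
        raise ValueError("at least one exclusion map is required")
    west, south, east, north = bounds
    nrow, ncol = shape
    dx = (east - west) / ncol
    dy = (north - south) / nrow

    rows_idx, cols_idx, outside = [], [], 0
    for lon, lat in zip(records["lon"], records["lat"]):
        if not (west <= lon <= east and south <= lat <= north):
            outside += 1
            rows_idx.append(-1)
            cols_idx.append(-1)
            continue
        rows_idx.append(min(int((north - lat) / dy), nrow - 1))
        cols_idx.append(min(int((lon - west) / dx), ncol - 1))
    rows_idx = np.array(rows_idx)
    cols_idx = np.array(cols_idx)
    in_extent = rows_idx >= 0

    out_rows = []
    pooled_used = pooled_included = pooled_nodata = 0
    for m in maps:
        combined = m.combined
        cats = np.full(len(records), CATEGORY_NODATA, dtype=int)
        cats[in_extent] = combined[rows_idx[in_extent], cols_idx[in_extent]]
        nodata = in_extent & (cats == CATEGORY_NODATA)
        used = in_extent & ~nodata
        included = used & (cats == CATEGORY_NONE)
        out_rows.append(
            {
                "year": m.year,
                "n_used": int(used.sum()),
                "n_outside": int(outside),
                "n_nodata": int(nodata.sum()),
                "included_fraction": (
                    included.sum() / used.sum() if used.any() else np.nan
                ),
            }
        )
        pooled_used += used.sum()
        pooled_included += included.sum()
        pooled_nodata += nodata.sum()
    out_rows.append(
        {
            "year": "overall",
            "n_used": int(pooled_used),
            "n_outside": int(outside * len(maps)),
            "n_nodata": int(pooled_nodata),
            "included_fraction": (
                pooled_included / pooled_used if pooled_used else np.nan
            ),
        }
    )
    return pd.DataFrame(out_rows)
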