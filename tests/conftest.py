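"""Shared fixtures: parameter sets, constant-temperature grids, oracles."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from slfrisk import SpeciesParams, SyntheticClimateSpec
from slfrisk.climate import DailyClimateGrid


@pytest.fixture
def params() -> SpeciesParams:
    return SpeciesParams()


def make_constant_grid(
    temp: float,
    year: int = 2023,
    shape: tuple[int, int] = (3, 3),
    diurnal: float = 0.0,
    n_days: int | None = None,
) -> DailyClimateGrid:
    """A grid held at a constant temperature all year."""
    start = date(year, 1, 1)
    if n_days is None:
        n_days = (date(year, 12, 31) - start).days + 1
    dates = [start + timedelta(days=i) for i in range(n_days)]
    base = np.full((n_days, *shape), float(temp))
    return DailyClimateGrid(
        tmin=base - diurnal / 2,
        tmax=base + diurnal / 2,
        dates=dates,
        bounds=(0.0, 40.0, float(shape[1]), 40.0 + shape[0]),
    )


@pytest.fixture
def constant_grid():
    return make_constant_grid


@pytest.fixture
def small_spec() -> SyntheticClimateSpec:
    """A small noisy synthetic-climate recipe for fast end-to-end runs."""
    return SyntheticClimateSpec(
        n_rows=6, n_cols=5, lat_min=32.0, lat_max=44.0, lon_min=-90.0,
        lon_max=-85.0, seed=7,
    )


def minute_triangle_trace(tmin: float, tmax: float, n: int = 1440) -> np.ndarray:
    """Temperature at n evenly spaced instants of a triangular day.

    The trace rises linearly from Tmin to Tmax over the first half of
    the day and falls back over the second half.
    """
    t = (np.arange(n) + 0.5) / n
    up = tmin + (tmax - tmin) * (2 * t)
    down = tmax - (tmax - tmin) * (2 * (t - 0.5))
    return np.where(t < 0.5, up, down)


def numeric_dd(tmin: float, tmax: float, ldt: float, udt: float) -> float:
    """Degree-days by 1-minute integration with horizontal UDT cutoff."""
    trace = minute_triangle_trace(tmin, tmax)
    return float(np.maximum(np.minimum(trace, udt) - ldt, 0.0).mean())


def numeric_stress(tmin: float, tmax: float, threshold: float, direction: str) -> float:
    """Stress units by 1-minute integration of the triangular trace."""
    trace = minute_triangle_trace(tmin, tmax)
    if direction == "cold":
        return float(np.maximum(threshold - trace, 0.0).mean())
    return float(np.maximum(trace - threshold, 0.0).mean())
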