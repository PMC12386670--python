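"""Single-triangle degree-days and thermal stress units.

The day's temperature trace is approximated by a triangle rising from
Tmin to Tmax and falling back, over one day of unit duration.  The area
of that trace above the lower developmental threshold (LDT), with
temperatures above the upper threshold (UDT) counted as if equal to the
UDT (horizontal cutoff), gives the day's degree-days.  Stress units use
the same triangular geometry: the area below a cold-stress threshold or
above a heat-stress threshold, with no second cutoff.

All functions are numpy-vectorised; scalars in give scalars out.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .params import ThermalThresholds

__all__ = ["single_triangle_dd", "stress_units", "triangle_area_above"]


def _as_float(x: ArrayLike) -> NDArray[np.float64]:
    return np.asarray(x, dtype=np.float64)


def triangle_area_above(
    tmin: ArrayLike, tmax: ArrayLike, threshold: float
) -> NDArray[np.float64] | float:
    """Area (degC-days) of the daily triangular trace above ``threshold``.

    Piecewise closed form: 0 when the whole day is below the threshold,
    the excess of the daily mean when the whole day is above it, and
    ``(tmax - threshold)^2 / (2 (tmax - tmin))`` when the threshold is
    crossed.  A zero diurnal range degenerates to constant temperature.
    """
    tn, tx = _as_float(tmin), _as_float(tmax)
    if np.any(tx < tn):
        raise ValueError("tmax < tmin")
    span = tx - tn
    # zero/tiny spans are masked out by the np.where below
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        crossing = (tx - threshold) ** 2 / (2.0 * span)
    area = np.where(
        tx <= threshold,
        0.0,
        np.where(
            tn >= threshold,
            (tn + tx) / 2.0 - threshold,
            np.where(span > 0.0, crossing, np.maximum(tx - threshold, 0.0)),
        ),
    )
    return area if area.ndim else float(area)


def single_triangle_dd(
    tmin: ArrayLike, tmax: ArrayLike, thresholds: ThermalThresholds
) -> NDArray[np.float64] | float:
    """Degree-days for one day by the single-triangle method.

    The horizontal cutoff at the upper threshold means the result is the
    area above the LDT minus the area above the UDT, bounded by
    ``udt - ldt`` for any day.
    """
    above_ldt = triangle_area_above(tmin, tmax, thresholds.ldt)
    above_udt = triangle_area_above(tmin, tmax, thresholds.udt)
    return above_ldt - above_udt


def stress_units(
    tmin: ArrayLike, tmax: ArrayLike, threshold: float, direction: str
) -> NDArray[np.float64] | float:
    """Daily stress units beyond a cold or heat stress threshold.

    ``direction="cold"``: area of the trace below the threshold, via the
    reflection T -> -T.  ``direction="heat"``: area above the threshold.
    """
    if direction == "heat":
        return triangle_area_above(tmin, tmax, threshold)
    if direction == "cold":
        tn, tx = _as_float(tmin), _as_float(tmax)
        return triangle_area_above(-tx, -tn, -threshold)
    raise ValueError(f"direction must be 'cold' or 'heat', got {direction!r}")
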