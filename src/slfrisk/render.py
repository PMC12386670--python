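"""PNG rendering of model rasters.

Styles follow the usual map conventions for this model family:
event maps use a continuous day-of-year colour ramp with
insufficient-accumulation cells in light gray; exclusion maps grey
moderate cells medium and severe cells dark; stress maps use a
sequential ramp; year-count maps a discrete ramp.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colors
from numpy.typing import NDArray

__all__ = ["render_map"]

_STYLES = {"event_doy", "stress", "exclusion", "year_count"}

LIGHT_GRAY = "#d9d9d9"
MEDIUM_GRAY = "#969696"
DARK_GRAY = "#525252"


def render_map(
    raster: NDArray,
    style: str,
    path: str | Path,
    bounds: tuple[float, float, float, float] | None = None,
    title: str = "",
    exclusion: NDArray | None = None,
) -> Path:
    """Render a raster to PNG with a legend.

    ``style`` is one of ``event_doy``, ``stress``, ``exclusion``,
    ``year_count``.  For ``event_doy``, NaN cells (event never occurs)
    are light gray, and an optional ``exclusion`` category raster
    (0/1/2) greys moderate/severe cells over the event colours.
    """
    if style not in _STYLES:
        raise ValueError(f"unknown style {style!r}; expected one of {sorted(_STYLES)}")
    raster = np.asarray(raster, dtype=float)
    extent = None
    if bounds is not None:
        west, south, east, north = bounds
        extent = (west, east, south, north)

    fig, ax = plt.subplots(figsize=(7, 5.5))
    all_nan = np.all(np.isnan(raster))

    if style == "exclusion":
        cmap = colors.ListedColormap(["#ffffcc", MEDIUM_GRAY, DARK_GRAY])
        norm = colors.BoundaryNorm([-0.5, 0.5, 1.5, 2.5], cmap.N)
        im = ax.imshow(raster, cmap=cmap, norm=norm, extent=extent)
        cbar = fig.colorbar(im, ax=ax, ticks=[0, 1, 2], shrink=0.8)
        cbar.ax.set_yticklabels(["suitable", "excl.-moderate", "excl.-severe"])
    else:
        cmap_name = {
            "event_doy": "viridis",
            "stress": "magma",
            "year_count": "YlGnBu",
        }[style]
        cmap = plt.get_cmap(cmap_name).copy()
        cmap.set_bad(LIGHT_GRAY)
        masked = np.ma.masked_invalid(raster)
        if style == "event_doy" and exclusion is not None:
            masked = np.ma.masked_where(exclusion > 0, masked)
        im = ax.imshow(masked, cmap=cmap, extent=extent)
        if style == "event_doy" and exclusion is not None:
            grey = colors.ListedColormap(["none", MEDIUM_GRAY, DARK_GRAY])
            norm = colors.BoundaryNorm([-0.5, 0.5, 1.5, 2.5], grey.N)
            ax.imshow(
                np.ma.masked_invalid(np.asarray(exclusion, dtype=float)),
                cmap=grey,
                norm=norm,
                extent=extent,
            )
        label = {
            "event_doy": "day of year",
            "stress": "stress units (degC-days)",
            "year_count": "years included",
        }[style]
        cbar = fig.colorbar(im, ax=ax, shrink=0.8)
        cbar.set_label(label)
        if style == "event_doy" and not all_nan:
            lo, hi = np.nanmin(raster), np.nanmax(raster)
            ax.set_xlabel(f"DOY range: {lo:.0f}-{hi:.0f}")

    if all_nan:
        ax.text(
            0.5, 0.5, "no data", transform=ax.transAxes,
            ha="center", va="center", color="gray",
        )
    if title:
        ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
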