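"""Parameter estimation for thresholds, stage durations, and cohorts.

Two procedures are provided.  The x-intercept method fits an ordinary
least-squares line to temperature vs. development-rate data
(``rate = a + b T``); the lower developmental threshold is the
x-intercept ``-a/b`` and the stage duration the reciprocal slope
``1/b`` in degree-days.  The cohort search scores candidate egg-hatch
distribution parameters (``xdist1``, ``distro_mean``, ``xdist2``)
against observed earliest and peak hatch dates by running the
phenology engine at each observation site, counting overpredictions
(predicted later than observed) and computing the mean absolute error
and bias in days; candidates are ranked by fewest overpredictions,
then MAE, then |bias|.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .climate import DailyClimateGrid
from .params import SpeciesParams
from .phenology import build_cohorts, run_annual_cycle

__all__ = [
    "x_intercept_fit",
    "CohortSearchGrid",
    "score_cohort_candidate",
    "select_cohort_params",
]


def x_intercept_fit(data: pd.DataFrame) -> tuple[float, float, float]:
    """Fit threshold and stage duration from rate data by OLS.

    ``data`` needs ``temperature`` (degC) and ``rate`` (1/days)
    columns.  Returns ``(lower_threshold_degC, duration_dd, r_squared)``.
    Raises if fewer than two distinct temperatures are present or the
    fitted slope is not positive (no positive thermal response).
    """
    temps = np.asarray(data["temperature"], dtype=float)
    rates = np.asarray(data["rate"], dtype=float)
    if np.any(rates < 0):
        raise ValueError("development rates must be >= 0")
    if len(np.unique(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures to fit a line")
    model = sm.OLS(rates, sm.add_constant(temps)).fit()
    a, b = model.params
    if b <= 0:
        raise ValueError(f"non-positive slope {b}: no positive thermal response")
    return float(-a / b), float(1.0 / b), float(model.rsquared)


def fit_all_stages(data: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`x_intercept_fit` per ``stage`` group."""
    rows = []
    for stage, group in data.groupby("stage"):
        ldt, dur, r2 = x_intercept_fit(group)
        rows.append(
            {"stage": stage, "lower_threshold": ldt, "duration_dd": dur, "r_squared": r2}
        )
    return pd.DataFrame(rows)


@dataclass
class CohortSearchGrid:
    """Candidate cohort-parameter triples for the grid search.

    The Cartesian product of the candidate values is filtered to
    triples with ``xdist1 < distro_mean < xdist2``; ``distro_var`` is
    held fixed across all candidates.
    """

    xdist1_values: list[float]
    distro_mean_values: list[float]
    xdist2_values: list[float]
    distro_var: float = 15000.0

    def candidates(self) -> list[tuple[float, float, float]]:
        out = [
            (x1, mu, x2)
            for x1, mu, x2 in product(
                self.xdist1_values, self.distro_mean_values, self.xdist2_values
            )
            if x1 < mu < x2
        ]
        if not out:
            raise ValueError("no valid candidate triples (need xdist1 < mean < xdist2)")
        return out


def _site_grid(climate: DailyClimateGrid, lon: float, lat: float) -> DailyClimateGrid:
    """A 1x1-cell grid holding one site's daily series."""
    row, col = climate.cell_index(lon, lat)
    dx, dy = climate.resolution
    west = climate.lons[col] - dx / 2
    north = climate.lats[row] + dy / 2
    return DailyClimateGrid(
        tmin=climate.tmin[:, row : row + 1, col : col + 1],
        tmax=climate.tmax[:, row : row + 1, col : col + 1],
        dates=list(climate.dates),
        bounds=(west, north - dy, west + dx, north),
        crs=climate.crs,
    )


def score_cohort_candidate(
    candidate: tuple[float, float, float],
    observations: pd.DataFrame,
    climate: DailyClimateGrid | dict[int, DailyClimateGrid],
    params: SpeciesParams | None = None,
    distro_var: float = 15000.0,
) -> tuple[int, float, float]:
    """Score one (xdist1, distro_mean, xdist2) candidate.

    ``observations`` needs ``lon``, ``lat`` and at least one of
    ``observed_first_hatch`` / ``observed_peak_hatch`` (DOY); a
    ``year`` column selects the grid when ``climate`` is a mapping.
    Earliest-cohort hatch is compared to the first-hatch observation
    and the cohort-weighted mean hatch to the peak observation.

    Returns ``(n_overpredictions, mae_days, bias_days)``.  A site where
    hatch is never predicted counts as an overprediction and is left
    out of the MAE/bias averages.
    """
    if params is None:
        params = SpeciesParams()
    x1, mu, x2 = candidate
    params = replace(params, xdist1=x1, distro_mean=mu, xdist2=x2, distro_var=distro_var)
    cohorts = build_cohorts(params)

    diffs: list[float] = []
    n_over = 0
    for _, rec in observations.iterrows():
        if isinstance(climate, dict):
            try:
                grid = climate[int(rec["year"])]
            except KeyError:
                raise ValueError(f"no climate for year {rec['year']}")
        else:
            grid = climate
        try:
            site = _site_grid(grid, rec["lon"], rec["lat"])
        except ValueError as err:
            raise ValueError(f"observation site outside climate extent: {err}")
        _, maps = run_annual_cycle(site, params, cohorts, keep_trajectory=False)
        for obs_col, pred_map in (
            ("observed_first_hatch", maps.earliest("egg_hatch")),
            ("observed_peak_hatch", maps.weighted_mean("egg_hatch")),
        ):
            if obs_col not in rec or pd.isna(rec.get(obs_col)):
                continue
            pred = float(pred_map[0, 0])
            obs = float(rec[obs_col])
            if np.isnan(pred):
                n_over += 1  # hatch never predicted: later than any observation
                continue
            if pred > obs:
                n_over += 1
            diffs.append(pred - obs)
    diffs_arr = np.array(diffs)
    mae = float(np.abs(diffs_arr).mean()) if len(diffs_arr) else float("nan")
    bias = float(diffs_arr.mean()) if len(diffs_arr) else float("nan")
    return n_over, mae, bias


def select_cohort_params(
    grid: CohortSearchGrid,
    observations: pd.DataFrame,
    climate: DailyClimateGrid | dict[int, DailyClimateGrid],
    params: SpeciesParams | None = None,
) -> tuple[tuple[float, float, float], pd.DataFrame]:
    """Rank cohort-parameter candidates and return the winner.

    Candidates are ordered by number of overpredictions, ties broken
    by MAE, then by |bias|.  Returns the best triple and the full
    score table sorted by rank.
    """
    rows = []
    for cand in grid.candidates():
        n_over, mae, bias = score_cohort_candidate(
            cand, observations, climate, params=params, distro_var=grid.distro_var
        )
        rows.append(
            {
                "xdist1": cand[0],
                "distro_mean": cand[1],
                "xdist2": cand[2],
                "n_overpredictions": n_over,
                "mae": mae,
                "bias": bias,
            }
        )
    table = pd.DataFrame(rows)
    table["abs_bias"] = table["bias"].abs()
    table = table.sort_values(
        ["n_overpredictions", "mae", "abs_bias"], kind="stable"
    ).drop(columns="abs_bias").reset_index(drop=True)
    best = table.iloc[0]
    return (float(best["xdist1"]), float(best["distro_mean"]), float(best["xdist2"])), table
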