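"""Cohort-structured degree-day phenology engine.

The life cycle starts on 1 January with overwintered eggs and runs one
generation (univoltine, obligate diapause): overwintered egg -> larva
(nymphal instars 1-4) -> pupa (pre-oviposition adult) -> adult
(first-to-50% oviposition) -> first-generation egg, which diapauses.
Within-population variation in egg development is modelled by a set of
cohorts whose hatch requirements discretise a normal distribution of
degree-days to complete overwintered-egg development.

Five phenological events are emitted per cohort and cell: egg hatch,
nymphs halfway developed, adult emergence, oviposition, and diapausing
egg.  Daily degree-days use the single-triangle method with the current
stage's thresholds; excess degree-days on a transition day carry into
the next stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from numpy.typing import NDArray

from .climate import DailyClimateGrid
from .degree_days import single_triangle_dd
from .params import SpeciesParams

__all__ = [
    "EVENTS",
    "CohortSet",
    "EventMaps",
    "CellTrajectory",
    "build_cohorts",
    "run_annual_cycle",
    "aggregate_cohort_events",
]

#: The five phenological events, in life-cycle order.
EVENTS = (
    "egg_hatch",
    "nymphs_halfway",
    "adult_emergence",
    "oviposition",
    "diapausing_egg",
)

# stage codes used in trajectories; DONE marks diapause (development halted)
STAGE_CODES = {"OE": 0, "L": 1, "P": 2, "A": 3, "E": 4}
DONE = 5
NO_CELL = -1  # missing climate


@dataclass(frozen=True)
class CohortSet:
    """Per-cohort overwintered-egg hatch requirements and weights.

    ``requirements`` (degC-days, strictly increasing) are the
    degree-days each cohort needs to complete egg development;
    ``weights`` are population fractions summing to 1.
    """

    requirements: NDArray[np.float64]
    weights: NDArray[np.float64]

    def __post_init__(self) -> None:
        req = np.asarray(self.requirements, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "requirements", req)
        object.__setattr__(self, "weights", w)
        if req.shape != w.shape or req.ndim != 1:
            raise ValueError("requirements and weights must be matching 1-D arrays")
        if not np.all(np.diff(req) > 0):
            raise ValueError("requirements must be strictly increasing")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    def __len__(self) -> int:
        return len(self.requirements)


def build_cohorts(params: SpeciesParams) -> CohortSet:
    """Discretise the egg-development distribution into cohorts.

    The range ``[xdist1, xdist2]`` is split into ``n_cohorts``
    equal-width bins; each cohort's requirement is its bin midpoint and
    its weight the normal probability mass
    (mean ``distro_mean``, variance ``distro_var``) of the bin,
    renormalised over the truncated range so weights sum to 1.
    """
    n = params.n_cohorts
    if n < 1:
        raise ValueError("n_cohorts must be >= 1")
    lo, hi = params.xdist1, params.xdist2
    if hi <= lo:
        raise ValueError("xdist2 must exceed xdist1")
    edges = np.linspace(lo, hi, n + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    dist = stats.norm(loc=params.distro_mean, scale=np.sqrt(params.distro_var))
    mass = np.diff(dist.cdf(edges))
    total = dist.cdf(hi) - dist.cdf(lo)
    return CohortSet(requirements=mids, weights=mass / total)


@dataclass
class EventMaps:
    """Per-cohort day-of-year rasters for the five phenological events.

    ``doy[event]`` has shape ``[cohort, row, col]``; NaN marks cells
    where the event never occurs in the modelled year (insufficient
    degree-day accumulation, or missing climate).
    """

    doy: dict[str, NDArray[np.float64]]
    weights: NDArray[np.float64]
    bounds: tuple[float, float, float, float]
    year: int

    def earliest(self, event: str) -> NDArray[np.float64]:
        return aggregate_cohort_events(self, event, "earliest")

    def weighted_mean(self, event: str) -> NDArray[np.float64]:
        return aggregate_cohort_events(self, event, "weighted_mean")

    def latest(self, event: str) -> NDArray[np.float64]:
        """DOY for the latest (highest-requirement) cohort with the event."""
        stack = self.doy[event]
        out = np.full(stack.shape[1:], np.nan)
        for k in range(stack.shape[0]):  # later cohorts overwrite
            layer = stack[k]
            ok = ~np.isnan(layer)
            out[ok] = layer[ok]
        return out


@dataclass
class CellTrajectory:
    """Daily per-cohort development state for every cell.

    ``stage[cohort, day, row, col]`` holds stage codes (0=OE, 1=L, 2=P,
    3=A, 4=E, 5=done, -1=missing climate); ``within_dd`` the degree-days
    accumulated within the current stage, and ``cum_dd`` the cumulative
    developmental degree-days since 1 January.
    """

    stage: NDArray[np.int8]
    within_dd: NDArray[np.float32]
    cum_dd: NDArray[np.float32]
    weights: NDArray[np.float64]

    def stage_on(self, doy: int) -> NDArray[np.int8]:
        """Stage codes on a 1-based day of year, ``[cohort, row, col]``."""
        return self.stage[:, doy - 1]

    def within_on(self, doy: int) -> NDArray[np.float32]:
        return self.within_dd[:, doy - 1]


def run_annual_cycle(
    grid: DailyClimateGrid,
    params: SpeciesParams,
    cohorts: CohortSet | None = None,
    keep_trajectory: bool = True,
) -> tuple[CellTrajectory | None, EventMaps]:
    """Step the cohort life cycle through one calendar year of climate.

    Each day, every active cohort accumulates single-triangle
    degree-days with its current stage's thresholds.  The overwintered
    egg completes when cumulative degree-days reach the cohort's hatch
    requirement (egg-hatch event); the larval, pupal and adult stages
    complete at their stage durations, emitting the nymphs-halfway,
    adult-emergence and oviposition events at their within-stage
    trigger points; the first-generation egg emits the diapausing-egg
    event, after which development halts (obligate diapause).  Excess
    degree-days on a transition day carry into the next stage, and a
    carry large enough to cross the next trigger fires it the same day.
    """
    year = grid.require_full_year()
    if cohorts is None:
        cohorts = build_cohorts(params)
    n_days = grid.n_days
    nrow, ncol = grid.shape
    n_coh = len(cohorts)
    valid = grid.valid_mask()

    # daily degree-days per stage; stages sharing thresholds share arrays
    dd_cache: dict[tuple[float, float], NDArray] = {}
    dd_by_stage: dict[int, NDArray] = {}
    for name, code in STAGE_CODES.items():
        thr = params.stage_thresholds(name)
        key = (thr.ldt, thr.udt)
        if key not in dd_cache:
            dd_cache[key] = np.asarray(
                single_triangle_dd(grid.tmin, grid.tmax, thr)
            )
        dd_by_stage[code] = dd_cache[key]

    durations = {
        STAGE_CODES["L"]: params.larvaeDD,
        STAGE_CODES["P"]: params.pupDD,
        STAGE_CODES["A"]: params.adultDD,
    }
    stage_events = {  # stage code -> (event name, within-stage trigger)
        STAGE_CODES["L"]: ("nymphs_halfway", params.larvaeEventDD),
        STAGE_CODES["P"]: ("adult_emergence", params.pupaeEventDD),
        STAGE_CODES["A"]: ("oviposition", params.adultEventDD),
        STAGE_CODES["E"]: ("diapausing_egg", params.eggEventDD),
    }

    event_doy = {
        ev: np.full((n_coh, nrow, ncol), np.nan) for ev in EVENTS
    }
    if keep_trajectory:
        traj_stage = np.full((n_coh, n_days, nrow, ncol), NO_CELL, dtype=np.int8)
        traj_within = np.zeros((n_coh, n_days, nrow, ncol), dtype=np.float32)
        traj_cum = np.zeros((n_coh, n_days, nrow, ncol), dtype=np.float32)

    for k in range(n_coh):
        req = cohorts.requirements[k]
        stage = np.where(valid, STAGE_CODES["OE"], NO_CELL).astype(np.int8)
        within = np.zeros((nrow, ncol))
        cum = np.zeros((nrow, ncol))
        for d in range(n_days):
            doy = d + 1
            active = (stage >= 0) & (stage < DONE)
            if active.any():
                dd_today = np.zeros((nrow, ncol))
                for code, dd in dd_by_stage.items():
                    sel = active & (stage == code)
                    if sel.any():
                        dd_today[sel] = dd[d][sel]
                within[active] += dd_today[active]
                cum[active] += dd_today[active]
                # resolve transitions; carried excess may cascade
                changed = True
                while changed:
                    changed = False
                    hatch = (stage == STAGE_CODES["OE"]) & (cum >= req)
                    if hatch.any():
                        _first(event_doy["egg_hatch"][k], hatch, doy)
                        # carry: DD beyond the requirement start the larva
                        within[hatch] = cum[hatch] - req
                        stage[hatch] = STAGE_CODES["L"]
                        changed = True
                    for code, (ev, trigger) in stage_events.items():
                        fired = (stage == code) & (within >= trigger)
                        if fired.any():
                            _first(event_doy[ev][k], fired, doy)
                    for code, dur in durations.items():
                        done_stage = (stage == code) & (within >= dur)
                        if done_stage.any():
                            within[done_stage] -= dur
                            stage[done_stage] += 1
                            changed = True
                    # diapausing egg: development halts at the event
                    halt = (stage == STAGE_CODES["E"]) & (
                        within >= params.eggEventDD
                    )
                    if halt.any():
                        stage[halt] = DONE
                        changed = True
            if keep_trajectory:
                traj_stage[k, d] = stage
                traj_within[k, d] = within
                traj_cum[k, d] = cum

    maps = EventMaps(
        doy=event_doy, weights=cohorts.weights, bounds=grid.bounds, year=year
    )
    traj = (
        CellTrajectory(traj_stage, traj_within, traj_cum, cohorts.weights)
        if keep_trajectory
        else None
    )
    return traj, maps


def _first(target: NDArray, mask: NDArray, doy: int) -> None:
    new = mask & np.isnan(target)
    target[new] = doy


def aggregate_cohort_events(
    maps: EventMaps,
    event: str,
    mode: Literal["earliest", "weighted_mean"],
) -> NDArray[np.float64]:
    """Collapse per-cohort event DOYs to one raster.

    ``earliest`` takes the minimum DOY over cohorts; ``weighted_mean``
    the cohort-weighted mean over cohorts in which the event occurred,
    with weights renormalised over those cohorts.  Cells where no
    cohort has the event are NaN.
    """
    if event not in maps.doy:
        raise KeyError(f"unknown event {event!r}")
    stack = maps.doy[event]
    if mode == "earliest":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            return np.where(
                np.isnan(stack).all(axis=0), np.nan, np.nanmin(stack, axis=0)
            )
    if mode == "weighted_mean":
        w = maps.weights[:, None, None]
        present = ~np.isnan(stack)
        wsum = np.where(present, w, 0.0).sum(axis=0)
        total = np.where(present, w * np.nan_to_num(stack), 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(wsum > 0, total / wsum, np.nan)
    raise ValueError(f"unknown mode {mode!r}")
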