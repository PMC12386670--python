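"""Validation of phenology predictions against field observations.

Two observation kinds are supported.  *First-date monitoring records*
give the observed first date of a phenological event; predicted vs.
observed days of year are summarised with MAE, bias, an OLS regression
of predicted on observed, and mean 95% confidence- and
prediction-interval lengths.  *Single-encounter records* (e.g.
citizen-science photographs) give only a date on which a life stage
was seen; these support one-sided paired Wilcoxon signed-rank tests of
whether a stage is predicted before it is observed (or, for
overwintered eggs, whether the last predicted hatch falls after the
observation) and a stage-concordance classification of the predicted
vs. observed life stage on the encounter date.
"""

from __future__ import annotations

import logging
import warnings
from datetime import date

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.typing import NDArray
from scipy import stats

from .phenology import DONE, NO_CELL, STAGE_CODES, CellTrajectory, EventMaps

__all__ = [
    "STAGE_CATEGORIES",
    "predict_at_records",
    "summarize_event_fit",
    "one_sided_encounter_test",
    "wilcoxon_one_sided",
    "stage_concordance",
    "classify_encounters",
]

log = logging.getLogger(__name__)

#: Observable life-stage categories in developmental order.
STAGE_CATEGORIES = ("egg_OW", "early_nymph", "late_nymph", "adult", "egg_G1")

# observation label -> (event, cohort aggregate) used for the prediction.
# First-appearance labels pair with the earliest cohort; overwintered
# eggs pair with the *last* egg hatch (latest cohort), the model's first
# event, which should fall after any OW-egg observation.
EVENT_FOR_LABEL: dict[str, tuple[str, str]] = {
    "egg_hatch": ("egg_hatch", "earliest"),
    "first_nymphs": ("egg_hatch", "earliest"),
    "early_nymph": ("egg_hatch", "earliest"),
    "nymphs_halfway": ("nymphs_halfway", "earliest"),
    "late_nymph": ("nymphs_halfway", "earliest"),
    "adult": ("adult_emergence", "earliest"),
    "adult_emergence": ("adult_emergence", "earliest"),
    "oviposition": ("oviposition", "earliest"),
    "egg_G1": ("oviposition", "earliest"),
    "diapausing_egg": ("diapausing_egg", "earliest"),
    "egg_OW": ("egg_hatch", "latest"),
}

#: Test direction per encounter label: first appearances should be
#: predicted no later than an encounter; last hatch after an OW egg.
DIRECTION_FOR_LABEL = {
    "early_nymph": "pred_before_obs",
    "late_nymph": "pred_before_obs",
    "adult": "pred_before_obs",
    "egg_G1": "pred_before_obs",
    "egg_OW": "pred_after_obs",
}


def _to_doy(value, year: int) -> int:
    if isinstance(value, str):
        value = date.fromisoformat(value)
    if isinstance(value, pd.Timestamp):
        value = value.date()
    if isinstance(value, date):
        if value.year != year:
            raise ValueError(f"observation date {value} outside modelled year {year}")
        return value.timetuple().tm_yday
    return int(value)


def _cell_index(bounds, shape, lon: float, lat: float) -> tuple[int, int]:
    west, south, east, north = bounds
    nrow, ncol = shape
    if not (west <= lon <= east and south <= lat <= north):
        raise ValueError(f"({lon}, {lat}) outside extent {bounds}")
    dx = (east - west) / ncol
    dy = (north - south) / nrow
    return (
        min(int((north - lat) / dy), nrow - 1),
        min(int((lon - west) / dx), ncol - 1),
    )


def predict_at_records(events: EventMaps, records: pd.DataFrame) -> pd.DataFrame:
    """Pair each observation with the model's prediction at its cell.

    ``records`` needs ``lon``, ``lat``, ``date`` (ISO string, date, or
    DOY) and ``label`` columns.  The prediction is the mapped event's
    DOY at the nearest cell (earliest cohort for first appearances,
    latest cohort for overwintered eggs).  Records outside the extent
    or on cells where the event never occurs are logged and skipped.
    """
    shape = next(iter(events.doy.values())).shape[1:]
    rasters: dict[str, NDArray] = {}
    rows = []
    for i, rec in records.iterrows():
        label = rec["label"]
        if label not in EVENT_FOR_LABEL:
            raise ValueError(f"unknown observation label {label!r}")
        event, agg = EVENT_FOR_LABEL[label]
        key = f"{event}:{agg}"
        if key not in rasters:
            rasters[key] = getattr(events, agg)(event)
        try:
            row, col = _cell_index(events.bounds, shape, rec["lon"], rec["lat"])
        except ValueError:
            log.warning("record %s outside extent, skipped", i)
            continue
        pred = float(rasters[key][row, col])
        if np.isnan(pred):
            log.warning("record %s: event %s never occurs at its cell", i, event)
            continue
        rows.append(
            {
                "label": label,
                "event": event,
                "doy_obs": _to_doy(rec["date"], events.year),
                "doy_pred": pred,
                "row": row,
                "col": col,
            }
        )
    return pd.DataFrame(rows)


def summarize_event_fit(pairs: pd.DataFrame) -> dict[str, float]:
    """Summary statistics for predicted vs. observed first dates.

    ``pairs`` needs ``doy_pred`` and ``doy_obs``.  Differences are
    ``pred - obs`` (days): MAE is the mean absolute difference, bias
    the mean difference, with its SD and range.  With >= 2 pairs an
    OLS regression of predicted on observed is fitted and the mean
    lengths of the pointwise 95% confidence and prediction intervals
    are reported; otherwise the regression fields are NaN.
    """
    pred = np.asarray(pairs["doy_pred"], dtype=float)
    obs = np.asarray(pairs["doy_obs"], dtype=float)
    if len(pred) < 1:
        raise ValueError("at least one pair required")
    diff = pred - obs
    out = {
        "n_obs": len(diff),
        "mae": float(np.abs(diff).mean()),
        "bias": float(diff.mean()),
        "sd": float(diff.std(ddof=1)) if len(diff) > 1 else float("nan"),
        "range_low": float(diff.min()),
        "range_high": float(diff.max()),
        "slope": float("nan"),
        "intercept": float("nan"),
        "mean_ci_length": float("nan"),
        "mean_pi_length": float("nan"),
    }
    if len(pred) >= 2 and len(np.unique(obs)) >= 2:
        model = sm.OLS(pred, sm.add_constant(obs)).fit()
        frame = model.get_prediction(sm.add_constant(obs)).summary_frame(alpha=0.05)
        out["intercept"], out["slope"] = (float(p) for p in model.params)
        out["mean_ci_length"] = float(
            (frame["mean_ci_upper"] - frame["mean_ci_lower"]).mean()
        )
        out["mean_pi_length"] = float(
            (frame["obs_ci_upper"] - frame["obs_ci_lower"]).mean()
        )
    return out


def _exact_signed_rank_cdf(n: int) -> NDArray[np.float64]:
    """Null PMF of the positive-rank sum W+ for n untied differences.

    Counts sign assignments by the standard generating-polynomial
    recursion; 2^n total assignments.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank] if rank else counts
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_one_sided(diffs: NDArray, alternative: str) -> float:
    """One-sided paired Wilcoxon signed-rank p-value on differences.

    ``alternative="less"`` tests whether the differences tend below
    zero, ``"greater"`` above.  Zero differences are dropped; with no
    ties and n <= 25 the exact null distribution is used, otherwise a
    normal approximation with continuity and tie corrections.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all differences are zero; p = 1")
        return 1.0
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if not has_ties and n <= 25:
        pmf = _exact_signed_rank_cdf(n)
        w = int(round(w_plus))
        if alternative == "less":
            return float(pmf[: w + 1].sum())
        if alternative == "greater":
            return float(pmf[w:].sum())
        raise ValueError(f"unknown alternative {alternative!r}")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if alternative == "less":
        z = (w_plus - mu + 0.5) / sd
        return float(stats.norm.cdf(z))
    if alternative == "greater":
        z = (w_plus - mu - 0.5) / sd
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown alternative {alternative!r}")


def one_sided_encounter_test(
    pairs: pd.DataFrame, direction: str
) -> dict[str, float]:
    """Directional test of predicted vs. observed encounter dates.

    ``direction="pred_before_obs"`` tests whether predictions fall
    significantly before observations (differences ``pred - obs``
    tend negative); ``"pred_after_obs"`` the reverse.  Returns the
    median predicted and observed DOYs, the percentage of pairs
    satisfying the direction, and the Wilcoxon p-value.
    """
    if direction == "pred_before_obs":
        alternative = "less"
    elif direction == "pred_after_obs":
        alternative = "greater"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    pred = np.asarray(pairs["doy_pred"], dtype=float)
    obs = np.asarray(pairs["doy_obs"], dtype=float)
    if len(pred) < 1:
        raise ValueError("at least one pair required")
    d = pred - obs
    satisfied = (d < 0) if alternative == "less" else (d > 0)
    return {
        "n_obs": len(d),
        "median_pred": float(np.median(pred)),
        "median_obs": float(np.median(obs)),
        "pct_in_direction": float(100.0 * satisfied.mean()),
        "p_value": wilcoxon_one_sided(d, alternative),
    }


def _stage_to_category(
    stage_code: int, within_dd: float, halfway_dd: float
) -> int:
    """Map an internal stage code to an observable category index."""
    if stage_code == STAGE_CODES["OE"]:
        return 0
    if stage_code == STAGE_CODES["L"]:
        return 1 if within_dd < halfway_dd else 2
    if stage_code in (STAGE_CODES["P"], STAGE_CODES["A"]):
        return 3  # pre-oviposition and ovipositing adults both look adult
    return 4  # first-generation egg (incl. diapause)


def stage_concordance(
    trajectory: CellTrajectory,
    doy: int,
    row: int,
    col: int,
    observed_label: str,
    mode: str = "modal",
    halfway_dd: float = 442.0,
) -> str | None:
    """Compare the model's life stage on a date with an observed stage.

    The predicted stage is the cohort-weighted modal category
    (``mode="modal"``) or the earliest cohort's category
    (``mode="earliest_cohort"``).  Returns ``"same"``,
    ``"model_older"`` (model ahead of the observation) or
    ``"model_younger"``; ``None`` for a missing-climate cell.
    """
    if observed_label not in STAGE_CATEGORIES:
        raise ValueError(f"unknown life-stage label {observed_label!r}")
    stages = trajectory.stage_on(doy)[:, row, col]
    within = trajectory.within_on(doy)[:, row, col]
    if np.all(stages == NO_CELL):
        return None
    cats = np.array(
        [
            _stage_to_category(int(s), float(w), halfway_dd)
            for s, w in zip(stages, within)
        ]
    )
    if mode == "earliest_cohort":
        pred_cat = int(cats[0])
    elif mode == "modal":
        mass = np.zeros(len(STAGE_CATEGORIES))
        for cat, w in zip(cats, trajectory.weights):
            mass[cat] += w
        pred_cat = int(mass.argmax())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    obs_cat = STAGE_CATEGORIES.index(observed_label)
    if pred_cat == obs_cat:
        return "same"
    return "model_older" if pred_cat > obs_cat else "model_younger"


def classify_encounters(
    trajectory: CellTrajectory,
    records: pd.DataFrame,
    bounds: tuple[float, float, float, float],
    year: int,
    mode: str = "modal",
    halfway_dd: float = 442.0,
) -> pd.DataFrame:
    """Stage concordance for a table of encounter records.

    ``records`` needs ``lon``, ``lat``, ``date`` and ``label``.
    Records outside the extent or on missing-climate cells are skipped
    with a log entry.
    """
    shape = trajectory.stage.shape[2:]
    rows = []
    for i, rec in records.iterrows():
        try:
            row, col = _cell_index(bounds, shape, rec["lon"], rec["lat"])
        except ValueError:
            log.warning("record %s outside extent, skipped", i)
            continue
        doy = _to_doy(rec["date"], year)
        verdict = stage_concordance(
            trajectory, doy, row, col, rec["label"], mode=mode, halfway_dd=halfway_dd
        )
        if verdict is None:
            log.warning("record %s on missing-climate cell, skipped", i)
            continue
        rows.append({"label": rec["label"], "doy": doy, "concordance": verdict})
    return pd.DataFrame(rows)
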