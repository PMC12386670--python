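"""Observation matching, fit summaries, Wilcoxon tests, stage concordance."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slfrisk import (
    SpeciesParams,
    one_sided_encounter_test,
    predict_at_records,
    run_annual_cycle,
    summarize_event_fit,
)
from slfrisk.validation import (
    STAGE_CATEGORIES,
    classify_encounters,
    stage_concordance,
    wilcoxon_one_sided,
)

from .conftest import make_constant_grid


@pytest.fixture(scope="module")
def warm_run():
    params = SpeciesParams()
    grid = make_constant_grid(25.0, shape=(2, 2))
    traj, maps = run_annual_cycle(grid, params)
    return grid, traj, maps


class TestPredictAtRecords:
    def test_cell_centre_lookup(self, warm_run):
        _, _, maps = warm_run
        records = pd.DataFrame(
            {"lon": [0.5], "lat": [40.5], "date": ["2023-05-01"],
             "label": ["egg_hatch"]}
        )
        pairs = predict_at_records(maps, records)
        assert pairs.loc[0, "doy_pred"] == 11.0
        assert pairs.loc[0, "doy_obs"] == 121

    def test_adult_encounter_uses_earliest_adult_emergence(self, warm_run):
        _, _, maps = warm_run
        records = pd.DataFrame(
            {"lon": [0.5], "lat": [40.5], "date": ["2023-08-01"], "label": ["adult"]}
        )
        pairs = predict_at_records(maps, records)
        assert pairs.loc[0, "event"] == "adult_emergence"
        assert pairs.loc[0, "doy_pred"] == maps.earliest("adult_emergence")[0, 0]

    def test_ow_egg_uses_latest_cohort_hatch(self, warm_run):
        _, _, maps = warm_run
        records = pd.DataFrame(
            {"lon": [0.5], "lat": [40.5], "date": ["2023-02-01"], "label": ["egg_OW"]}
        )
        pairs = predict_at_records(maps, records)
        assert pairs.loc[0, "doy_pred"] == maps.doy["egg_hatch"][-1, 0, 0]

    def test_never_occurring_event_skipped(self, caplog):
        grid = make_constant_grid(12.0, shape=(1, 1))  # no adults all year
        _, maps = run_annual_cycle(grid, SpeciesParams(), keep_trajectory=False)
        records = pd.DataFrame(
            {"lon": [0.5], "lat": [40.5], "date": ["2023-08-01"], "label": ["adult"]}
        )
        with caplog.at_level("WARNING"):
            pairs = predict_at_records(maps, records)
        assert pairs.empty
        assert "never occurs" in caplog.text

    def test_out_of_extent_skipped_and_unknown_label_raises(self, warm_run):
        _, _, maps = warm_run
        records = pd.DataFrame(
            {"lon": [99.0], "lat": [40.5], "date": ["2023-05-01"],
             "label": ["egg_hatch"]}
        )
        assert predict_at_records(maps, records).empty
        records["lon"] = 0.5
        records["label"] = ["imago"]
        with pytest.raises(ValueError, match="unknown observation label"):
            predict_at_records(maps, records)


class TestSummarizeEventFit:
    def test_mae_and_bias_arithmetic(self):
        pairs = pd.DataFrame({"doy_pred": [98.0, 100.0, 102.0],
                              "doy_obs": [100.0, 100.0, 100.0]})
        out = summarize_event_fit(pairs)
        assert out["mae"] == pytest.approx(4.0 / 3.0)
        assert out["bias"] == pytest.approx(0.0)
        assert (out["range_low"], out["range_high"]) == (-2.0, 2.0)

    def test_perfect_predictions(self):
        obs = np.array([100.0, 120.0, 140.0, 160.0])
        pairs = pd.DataFrame({"doy_pred": obs, "doy_obs": obs})
        out = summarize_event_fit(pairs)
        assert out["mae"] == 0.0 and out["bias"] == 0.0
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        obs = rng.uniform(100, 200, 12)
        pred = obs + rng.normal(0, 5, 12)
        pairs = pd.DataFrame({"doy_pred": pred, "doy_obs": obs})
        shuffled = pairs.sample(frac=1, random_state=2).reset_index(drop=True)
        a, b = summarize_event_fit(pairs), summarize_event_fit(shuffled)
        for key in ("mae", "bias", "slope", "mean_pi_length"):
            assert a[key] == pytest.approx(b[key])

    def test_pi_wider_than_ci_and_mae_bounds_bias(self):
        rng = np.random.default_rng(4)
        obs = rng.uniform(100, 200, 20)
        pairs = pd.DataFrame(
            {"doy_pred": obs + rng.normal(0, 6, 20), "doy_obs": obs}
        )
        out = summarize_event_fit(pairs)
        assert out["mean_pi_length"] > out["mean_ci_length"]
        assert out["mae"] >= abs(out["bias"])

    def test_single_pair_no_regression(self):
        out = summarize_event_fit(
            pd.DataFrame({"doy_pred": [100.0], "doy_obs": [90.0]})
        )
        assert out["mae"] == 10.0
        assert np.isnan(out["slope"])

    def test_prediction_interval_empirical_coverage(self):
        """95% PI covers ~95% of held-out points under the Gaussian model."""
        rng = np.random.default_rng(2024)
        n_train, sigma = 30, 5.0
        hits = 0
        n_rep = 400
        import statsmodels.api as sm

        for _ in range(n_rep):
            x = rng.uniform(100, 200, n_train)
            y = 0.9 * x + 10 + rng.normal(0, sigma, n_train)
            model = sm.OLS(y, sm.add_constant(x)).fit()
            x_new = rng.uniform(100, 200)
            y_new = 0.9 * x_new + 10 + rng.normal(0, sigma)
            frame = model.get_prediction([1.0, x_new]).summary_frame(alpha=0.05)
            hits += int(frame["obs_ci_lower"][0] <= y_new <= frame["obs_ci_upper"][0])
        assert hits / n_rep == pytest.approx(0.95, abs=0.03)


class TestWilcoxon:
    def test_all_negative_n5_exact(self):
        # all 5 differences negative: W+ = 0, exact p = 1/2^5
        diffs = np.array([-3.0, -1.0, -4.0, -2.0, -5.0])
        assert wilcoxon_one_sided(diffs, "less") == pytest.approx(1.0 / 32.0)

    def test_single_difference(self):
        assert wilcoxon_one_sided(np.array([-2.0]), "less") == pytest.approx(0.5)
        assert wilcoxon_one_sided(np.array([-2.0]), "greater") == pytest.approx(1.0)

    def test_symmetric_diffs_no_signal(self):
        diffs = np.array([-3.0, 3.1, -1.0, 1.1])
        assert wilcoxon_one_sided(diffs, "less") >= 0.5 - 1e-12

    def test_zeros_dropped_all_zero_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_one_sided(np.zeros(4), "less") == 1.0

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_exact_matches_brute_force_enumeration(self, n):
        """Exact p equals direct enumeration of all 2^n sign patterns."""
        rng = np.random.default_rng(n)
        mags = np.sort(rng.uniform(0.5, 10.0, n))  # untied magnitudes
        signs = rng.choice([-1.0, 1.0], n)
        diffs = signs * mags
        ranks = np.arange(1, n + 1)
        w_obs = ranks[signs > 0].sum()
        count = sum(
            1
            for pattern in product([0, 1], repeat=n)
            if (ranks * np.array(pattern)).sum() <= w_obs
        )
        assert wilcoxon_one_sided(diffs, "less") == pytest.approx(count / 2**n)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(9)
        diffs = rng.uniform(0.5, 9.5, 12) * rng.choice([-1, 1], 12)
        want = stats.wilcoxon(diffs, alternative="less", mode="exact").pvalue
        assert wilcoxon_one_sided(diffs, "less") == pytest.approx(want)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(10)
        diffs = rng.normal(-1.0, 2.0, 60)
        diffs = diffs[diffs != 0]
        got = wilcoxon_one_sided(diffs, "less")
        want = stats.wilcoxon(
            diffs, alternative="less", mode="approx", correction=True
        ).pvalue
        assert got == pytest.approx(want, rel=1e-6)

    def test_encounter_test_reports_medians_and_direction(self):
        pairs = pd.DataFrame(
            {"doy_pred": [100.0, 110.0, 120.0], "doy_obs": [130.0, 135.0, 118.0]}
        )
        out = one_sided_encounter_test(pairs, "pred_before_obs")
        assert out["median_pred"] == 110.0
        assert out["median_obs"] == 130.0
        assert out["pct_in_direction"] == pytest.approx(100 * 2 / 3)
        with pytest.raises(ValueError, match="direction"):
            one_sided_encounter_test(pairs, "sideways")


class TestStageConcordance:
    def test_before_any_hatch_is_ow_egg(self, warm_run):
        _, traj, _ = warm_run
        assert stage_concordance(traj, 5, 0, 0, "egg_OW") == "same"

    def test_model_older_when_adult_predicted_for_late_nymph(self, warm_run):
        _, traj, maps = warm_run
        doy = int(np.nanmax(maps.doy["oviposition"][:, 0, 0])) + 5
        assert stage_concordance(traj, doy, 0, 0, "late_nymph") == "model_older"

    def test_early_vs_late_nymph_split_at_halfway(self, warm_run):
        _, traj, maps = warm_run
        hatch = int(maps.doy["egg_hatch"][0, 0, 0])
        halfway = int(maps.doy["nymphs_halfway"][0, 0, 0])
        assert (
            stage_concordance(traj, hatch + 1, 0, 0, "early_nymph",
                              mode="earliest_cohort")
            == "same"
        )
        assert (
            stage_concordance(traj, halfway, 0, 0, "late_nymph",
                              mode="earliest_cohort")
            == "same"
        )

    def test_self_consistent_encounters_all_same(self, warm_run):
        """Encounters sampled from the model's own modal stage agree 100%."""
        grid, traj, _ = warm_run
        rng = np.random.default_rng(6)
        rows = []
        for doy in rng.integers(1, 366, 40):
            mass = np.zeros(len(STAGE_CATEGORIES))
            stages = traj.stage_on(int(doy))[:, 0, 0]
            within = traj.within_on(int(doy))[:, 0, 0]
            from slfrisk.validation import _stage_to_category

            for s, w, wt in zip(stages, within, traj.weights):
                mass[_stage_to_category(int(s), float(w), 442.0)] += wt
            rows.append(
                {"lon": 0.5, "lat": 40.5, "date": int(doy),
                 "label": STAGE_CATEGORIES[int(mass.argmax())]}
            )
        table = classify_encounters(
            traj, pd.DataFrame(rows), grid.bounds, 2023
        )
        assert (table["concordance"] == "same").all()

    def test_unknown_label_raises(self, warm_run):
        _, traj, _ = warm_run
        with pytest.raises(ValueError, match="life-stage label"):
            stage_concordance(traj, 10, 0, 0, "larva")
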