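"""Cohort construction and the annual life-cycle engine."""

import numpy as np
import pytest

from slfrisk import (
    EVENTS,
    CohortSet,
    EventMaps,
    SpeciesParams,
    aggregate_cohort_events,
    build_cohorts,
    generate_synthetic_climate,
    run_annual_cycle,
    SyntheticClimateSpec,
)

from .conftest import make_constant_grid


class TestBuildCohorts:
    def test_default_seven_cohorts_within_bounds(self, params):
        cohorts = build_cohorts(params)
        assert len(cohorts) == 7
        assert cohorts.requirements.min() >= params.xdist1
        assert cohorts.requirements.max() <= params.xdist2
        assert np.all(np.diff(cohorts.requirements) > 0)

    def test_weights_sum_to_one(self, params):
        assert build_cohorts(params).weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_match_numeric_density_integration(self, params):
        """Bin masses against trapezoid integration of the normal density."""
        cohorts = build_cohorts(params)
        mu, sigma = params.distro_mean, np.sqrt(params.distro_var)

        def density(x):
            return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (
                sigma * np.sqrt(2 * np.pi)
            )

        edges = np.linspace(params.xdist1, params.xdist2, 8)
        masses = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            x = np.linspace(lo, hi, 20001)
            masses.append(np.trapezoid(density(x), x))
        masses = np.array(masses)
        masses /= masses.sum()
        np.testing.assert_allclose(cohorts.weights, masses, atol=1e-6)

    def test_invalid_cohort_setups_raise(self):
        with pytest.raises(ValueError):
            SpeciesParams(n_cohorts=0)
        with pytest.raises(ValueError):
            SpeciesParams(xdist1=360.0, xdist2=135.0)
        with pytest.raises(ValueError):
            CohortSet(requirements=np.array([2.0, 1.0]), weights=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            CohortSet(requirements=np.array([1.0, 2.0]), weights=np.array([0.5, 0.6]))


class TestAnnualCycle:
    def test_constant_25C_event_days(self, params):
        """Frozen hand computation: daily DD = 15, first requirement
        135 + (225/7)/2, so hatch on day 11 and the carried excess walks
        the later events to days 40, 70, 112 and 128."""
        grid = make_constant_grid(25.0, shape=(2, 2))
        _, maps = run_annual_cycle(grid, params, keep_trajectory=False)
        first = {ev: maps.doy[ev][0, 0, 0] for ev in EVENTS}
        assert first == {
            "egg_hatch": 11.0,
            "nymphs_halfway": 40.0,
            "adult_emergence": 70.0,
            "oviposition": 112.0,
            "diapausing_egg": 128.0,
        }

    def test_below_threshold_year_is_all_nodata(self, params):
        grid = make_constant_grid(9.0, shape=(2, 2))
        _, maps = run_annual_cycle(grid, params, keep_trajectory=False)
        for ev in EVENTS:
            assert np.isnan(maps.doy[ev]).all()

    def test_insufficient_accumulation_never_reaches_adult(self, params):
        # 12 degC all year: 2 DD/day, 730 DD/year < 890 + smallest
        # hatch requirement, so eggs hatch but no adult ever emerges
        grid = make_constant_grid(12.0, shape=(1, 1))
        _, maps = run_annual_cycle(grid, params, keep_trajectory=False)
        assert not np.isnan(maps.doy["egg_hatch"][0]).all()
        assert np.isnan(maps.doy["adult_emergence"]).all()

    def test_single_cohort_closed_form_hatch(self, params):
        cohorts = CohortSet(
            requirements=np.array([params.distro_mean]), weights=np.array([1.0])
        )
        grid = make_constant_grid(25.0, shape=(1, 1))
        _, maps = run_annual_cycle(grid, params, cohorts, keep_trajectory=False)
        expected = int(np.ceil(params.distro_mean / 15.0))  # 190/15 -> day 13
        assert maps.doy["egg_hatch"][0, 0, 0] == expected
        np.testing.assert_array_equal(
            maps.earliest("egg_hatch"), maps.weighted_mean("egg_hatch")
        )

    def test_warmer_never_later(self, params):
        cold = make_constant_grid(20.0, shape=(1, 1))
        warm = make_constant_grid(25.0, shape=(1, 1))
        _, m_cold = run_annual_cycle(cold, params, keep_trajectory=False)
        _, m_warm = run_annual_cycle(warm, params, keep_trajectory=False)
        for ev in EVENTS:
            a, b = m_warm.doy[ev], m_cold.doy[ev]
            both = ~np.isnan(a) & ~np.isnan(b)
            assert np.all(a[both] <= b[both])
            # anything the cold run achieves, the warm run achieves too
            assert not np.any(np.isnan(a) & ~np.isnan(b))

    def test_event_ordering_on_noisy_synthetic_grid(self, params, small_spec):
        grid = generate_synthetic_climate(small_spec, 2023)
        _, maps = run_annual_cycle(grid, params, keep_trajectory=False)
        order = [maps.doy[ev] for ev in EVENTS]
        for earlier, later in zip(order, order[1:]):
            both = ~np.isnan(earlier) & ~np.isnan(later)
            assert np.all(earlier[both] <= later[both])

    def test_first_adult_doy_nondecreasing_with_latitude(self, params):
        spec = SyntheticClimateSpec(
            n_rows=8, n_cols=3, noise_sd=0.0, lapse_per_degree=0.8,
            lat_min=30.0, lat_max=46.0,
        )
        grid = generate_synthetic_climate(spec, 2023)
        _, maps = run_annual_cycle(grid, params, keep_trajectory=False)
        adult = maps.earliest("adult_emergence")
        for col in range(3):
            south_to_north = adult[::-1, col]  # increasing latitude
            seen = south_to_north[~np.isnan(south_to_north)]
            assert np.all(np.diff(seen) >= 0)
            # NaN (insufficient accumulation) only at the cold end
            nan_mask = np.isnan(south_to_north)
            if nan_mask.any():
                assert nan_mask[np.argmax(nan_mask):].all()

    def test_trajectory_stage_monotone_and_consistent(self, params):
        grid = make_constant_grid(25.0, shape=(1, 1))
        traj, maps = run_annual_cycle(grid, params)
        for k in range(traj.stage.shape[0]):
            stages = traj.stage[k, :, 0, 0]
            assert np.all(np.diff(stages) >= 0)
            hatch = maps.doy["egg_hatch"][k, 0, 0]
            assert stages[int(hatch) - 2] == 0 and stages[int(hatch) - 1] == 1

    def test_nodata_cell_emits_no_events(self, params):
        grid = make_constant_grid(25.0, shape=(2, 2))
        grid.tmin[100, 0, 0] = np.nan
        grid.tmax[100, 0, 0] = np.nan
        _, maps = run_annual_cycle(grid, params, keep_trajectory=False)
        assert np.isnan(maps.doy["egg_hatch"][:, 0, 0]).all()
        assert not np.isnan(maps.doy["egg_hatch"][:, 1, 1]).any()


class TestAggregateCohortEvents:
    @staticmethod
    def make_maps(doys, weights):
        stack = np.asarray(doys, dtype=float)[:, None, None]
        return EventMaps(
            doy={"egg_hatch": stack},
            weights=np.asarray(weights, dtype=float),
            bounds=(0, 0, 1, 1),
            year=2023,
        )

    def test_earliest_and_mean(self):
        maps = self.make_maps([10.0, 20.0], [0.5, 0.5])
        assert aggregate_cohort_events(maps, "egg_hatch", "earliest")[0, 0] == 10.0
        assert aggregate_cohort_events(maps, "egg_hatch", "weighted_mean")[0, 0] == 15.0

    def test_missing_cohort_renormalised(self):
        maps = self.make_maps([10.0, np.nan, 30.0], [0.25, 0.5, 0.25])
        got = aggregate_cohort_events(maps, "egg_hatch", "weighted_mean")[0, 0]
        assert got == pytest.approx((0.25 * 10 + 0.25 * 30) / 0.5)

    def test_no_cohort_gives_nodata(self):
        maps = self.make_maps([np.nan, np.nan], [0.5, 0.5])
        assert np.isnan(aggregate_cohort_events(maps, "egg_hatch", "earliest")[0, 0])

    def test_unknown_mode_and_event_raise(self):
        maps = self.make_maps([10.0], [1.0])
        with pytest.raises(ValueError, match="mode"):
            aggregate_cohort_events(maps, "egg_hatch", "median")
        with pytest.raises(KeyError):
            aggregate_cohort_events(maps, "moulting", "earliest")
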