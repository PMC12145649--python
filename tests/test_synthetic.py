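"""Synthetic study-frame generator tests: weather, regions, counts."""

import numpy as np
import pandas as pd
import pytest

import heatcrossover as hc
from heatcrossover.design import build_strata
from heatcrossover.spatial import compute_weights
from heatcrossover.synthetic import (
    SimConfig,
    negative_binomial_counts,
    regions_from_geojson,
    regions_to_geojson,
    simulate_stratum_counts,
)


class TestSimConfig:
    def test_invalid_parameters_rejected_by_name(self):
        with pytest.raises(ValueError, match="noise_sd"):
            SimConfig(noise_sd=float("nan"))
        with pytest.raises(ValueError, match="daily_ar1_rho"):
            SimConfig(daily_ar1_rho=1.0)
        with pytest.raises(ValueError, match="overdispersion"):
            SimConfig(overdispersion=0.5)
        with pytest.raises(ValueError, match="months"):
            SimConfig(months=frozenset({0, 5}))

    def test_substreams_are_independent_and_reproducible(self):
        a = SimConfig(seed=7).streams()
        b = SimConfig(seed=7).streams()
        assert a["weather"].standard_normal(5) == pytest.approx(
            b["weather"].standard_normal(5)
        )
        assert not np.allclose(
            SimConfig(seed=7).streams()["weather"].standard_normal(5),
            SimConfig(seed=7).streams()["counts"].standard_normal(5),
        )


class TestWarmSeasonCalendar:
    def test_leadin_days_precede_each_season(self):
        cal = hc.warm_season_calendar(SimConfig(n_years=2))
        leadins = cal[~cal["analysed"]]
        assert len(leadins) == 2 * 2
        assert all(d.month == 4 for d in leadins["date"])

    def test_analysed_days_cover_may_to_september(self):
        cal = hc.warm_season_calendar(SimConfig(n_years=1, start_year=2005))
        analysed = cal[cal["analysed"]]
        assert len(analysed) == 153  # 31+30+31+31+30
        assert set(pd.DatetimeIndex(analysed["date"]).month) == {5, 6, 7, 8, 9}


class TestSimulateWeather:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(n_years=1, grid_shape=(4, 4), n_regions=4, seed=1)
        a = hc.simulate_weather(cfg)
        b = hc.simulate_weather(cfg)
        assert np.array_equal(a["tmax"].values, b["tmax"].values)
        assert np.array_equal(a["vp"].values, b["vp"].values)

    def test_degenerate_noise_gives_pure_sinusoid(self):
        cfg = SimConfig(
            n_years=1,
            grid_shape=(3, 3),
            n_regions=4,
            noise_sd=0.0,
            daily_ar1_rho=0.0,
            spatial_sd=0.0,
            burst_rate=0.0,
            seed=2,
        )
        grid = hc.simulate_weather(cfg)
        tmax = grid["tmax"].values
        # identical across cells, and equal to the seasonal curve
        assert np.allclose(tmax, tmax[:, :1, :1])
        from heatcrossover.synthetic import _seasonal_mean

        cal = hc.warm_season_calendar(cfg)
        expected = _seasonal_mean(pd.DatetimeIndex(cal["date"]), cfg)
        assert np.allclose(tmax[:, 0, 0], expected)

    def test_tmax_dominates_tmean_and_vp_below_saturation(self, small_frame):
        grid = small_frame["grid"]
        assert (grid["tmax"].values >= grid["tmean"].values).all()
        vp = grid["vp"].values
        from heatcrossover.spatial import saturation_vapour_pressure

        assert (vp > 0).all()
        assert (vp <= saturation_vapour_pressure(grid["tmean"].values)).all()

    def test_lag1_autocorrelation_recovers_ar_coefficient(self, default_frame):
        # sample autocorrelation of deseasonalised tmax over >=1000 days
        grid = default_frame["grid"]
        sim = default_frame["sim"]
        t = grid["tmax"].values.reshape(grid.data.sizes["date"], -1)
        dates = pd.DatetimeIndex(grid["date"].values)
        doy, years = dates.dayofyear, dates.year
        deseas = t - pd.DataFrame(t).groupby(doy).transform("mean").values
        same_season = np.asarray(years[1:]) == np.asarray(years[:-1])
        acs = []
        for c in range(0, t.shape[1], 13):
            x = deseas[:, c]
            acs.append(np.corrcoef(x[:-1][same_season], x[1:][same_season])[0, 1])
        assert np.mean(acs) == pytest.approx(sim.daily_ar1_rho, abs=0.1)

    def test_exceedance_runs_in_most_region_seasons(self, default_frame):
        # the generator must make two-day 99th-percentile runs common enough
        # that exposure is non-degenerate in at least half the region-seasons
        expo = default_frame["exposure"]
        expo = expo.assign(year=pd.DatetimeIndex(expo["date"]).year)
        coverage = expo.groupby(["region_id", "year"])["ehe_p99"].max().mean()
        assert coverage >= 0.5


class TestSimulateRegions:
    def test_pixel_fractions_for_aligned_region(self):
        cfg = SimConfig(n_years=1, grid_shape=(4, 4), n_regions=4, seed=3)
        grid = hc.simulate_weather(cfg)
        regions = hc.simulate_regions(cfg, grid)
        # all but the first region are aligned to whole cells
        aligned = regions["R01"]["polygon"]
        w = compute_weights(aligned, grid.geometry, "R01")
        assert all(v == pytest.approx(1.0 / len(w.cell_weights)) for v in w.cell_weights.values())

    def test_first_region_cuts_cells(self, small_frame):
        poly = small_frame["regions"]["R00"]["polygon"]
        w = compute_weights(poly, small_frame["grid"].geometry, "R00")
        assert len(set(np.round(list(w.cell_weights.values()), 12))) > 1

    def test_ecumene_fraction_between_30_and_100_percent(self, small_frame):
        for region_id, geoms in small_frame["regions"].items():
            frac = geoms["ecumene"].area / geoms["polygon"].area
            assert 0.3 <= frac <= 1.0 + 1e-12, region_id

    def test_regions_do_not_overlap(self, small_frame):
        ids = list(small_frame["regions"])
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                inter = (
                    small_frame["regions"][a]["polygon"]
                    .intersection(small_frame["regions"][b]["polygon"])
                    .area
                )
                assert inter == pytest.approx(0.0, abs=1e-12)

    def test_capacity_exceeded_raises(self):
        cfg = SimConfig(n_years=1, grid_shape=(4, 4), n_regions=4, seed=3)
        grid = hc.simulate_weather(cfg)
        over = SimConfig(n_years=1, grid_shape=(4, 4), n_regions=400, seed=3)
        with pytest.raises(ValueError, match="n_regions"):
            hc.simulate_regions(over, grid)

    def test_geojson_roundtrip(self, small_frame):
        doc = regions_to_geojson(small_frame["regions"])
        back = regions_from_geojson(doc)
        for rid, geoms in small_frame["regions"].items():
            assert back[rid]["polygon"].equals(geoms["polygon"])
            assert back[rid]["ecumene"].equals(geoms["ecumene"])


class TestCounts:
    def test_phi_below_one_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="phi"):
            negative_binomial_counts(rng, np.array([2.0]), 0.5)

    def test_moment_match_mean_and_variance(self):
        # fixed stratum: empirical mean ~ mu and variance ~ phi*mu (3 MC SEs)
        rng = np.random.default_rng(10)
        mu, phi, n = 3.0, 2.5, 40_000
        y = negative_binomial_counts(rng, np.full(n, mu), phi)
        se_mean = np.sqrt(phi * mu / n)
        assert abs(y.mean() - mu) < 3 * se_mean
        var = y.var(ddof=1)
        se_var = np.sqrt(2.0 / n) * phi * mu * 2  # generous MC bound
        assert abs(var - phi * mu) < 3 * se_var

    def test_poisson_limit_dispersion_index(self):
        rng = np.random.default_rng(11)
        mu, n = 2.0, 40_000
        y = negative_binomial_counts(rng, np.full(n, mu), 1.0)
        index = y.var(ddof=1) / y.mean()
        assert index == pytest.approx(1.0, abs=0.03)

    def test_null_effect_gives_unit_rate_ratio(self):
        rng = np.random.default_rng(12)
        n = 100_000
        x = (rng.random(n) < 0.3).astype(int)
        codes = np.repeat(np.arange(n // 5), 5)
        y = simulate_stratum_counts(rng, x, codes, 0.0, 2.0, 1.5, alpha_sd=0.0)
        rr = y[x == 1].mean() / y[x == 0].mean()
        se = np.sqrt(1.5 / y[x == 1].sum() + 1.5 / y[x == 0].sum())  # delta-method on log RR
        assert abs(np.log(rr)) < 2 * se + 0.01

    def test_records_deterministic_and_schema(self, small_frame, small_counts):
        records = small_counts["records"]
        assert list(records.columns) == [
            "date",
            "region_id",
            "icd10_primary",
            "icd10_secondary",
            "age_group",
            "sex",
            "count",
        ]
        sim = small_frame["sim"]
        expo = small_frame["exposure"]
        strata = build_strata(expo[["region_id", "date"]])["stratum_id"]
        again = hc.simulate_counts(sim, expo, strata)
        pd.testing.assert_frame_equal(records, again)

    def test_confounded_crude_rr_but_conditional_recovery(self):
        # stratum confounding biases the crude pooled RR; the conditional
        # fit recovers the embedded log(1.29)
        from heatcrossover.design import filter_informative
        from heatcrossover.synthetic import recovery_table

        rng = np.random.default_rng(13)
        betas = []
        for _ in range(60):
            table = recovery_table(rng, n_strata=400)
            inf, _ = filter_informative(table)
            betas.append(hc.fit(inf).beta[0])
        mean = np.mean(betas)
        mcse = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(mean - np.log(1.29)) < 2 * mcse
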