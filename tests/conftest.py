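import numpy as np
import pandas as pd
import pytest

import heatcrossover as hc
from heatcrossover.design import build_strata


@pytest.fixture(scope="session")
def small_sim():
    """Compact study frame: 3 years, 8x8 grid, 4 regions."""
    return hc.SimConfig(
        n_years=3, grid_shape=(8, 8), n_regions=4, seed=12345
    )


@pytest.fixture(scope="session")
def default_sim():
    """The full ten-year default frame."""
    return hc.SimConfig()


@pytest.fixture(scope="session")
def small_frame(small_sim):
    """Weather → regions → region series → thresholds → exposure, shared."""
    grid = hc.simulate_weather(small_sim)
    regions = hc.simulate_regions(small_sim, grid)
    series = hc.build_region_series(grid, regions, grid.geometry)
    series = series.merge(hc.warm_season_calendar(small_sim), on="date", how="left")
    thresholds = hc.compute_thresholds(series)
    exposure = hc.build_exposure_series(series, thresholds)
    return {
        "sim": small_sim,
        "grid": grid,
        "regions": regions,
        "series": series,
        "thresholds": thresholds,
        "exposure": exposure,
    }


@pytest.fixture(scope="session")
def default_frame(default_sim):
    grid = hc.simulate_weather(default_sim)
    regions = hc.simulate_regions(default_sim, grid)
    series = hc.build_region_series(grid, regions, grid.geometry)
    series = series.merge(hc.warm_season_calendar(default_sim), on="date", how="left")
    thresholds = hc.compute_thresholds(series)
    exposure = hc.build_exposure_series(series, thresholds)
    return {
        "sim": default_sim,
        "grid": grid,
        "regions": regions,
        "series": series,
        "thresholds": thresholds,
        "exposure": exposure,
    }


@pytest.fixture(scope="session")
def small_counts(small_frame):
    sim = small_frame["sim"]
    exposure = small_frame["exposure"]
    strata = build_strata(exposure[["region_id", "date"]])["stratum_id"]
    records = hc.simulate_counts(sim, exposure, strata)
    counts = hc.aggregate_counts(
        records, hc.default_taxonomy(), exposure[["region_id", "date"]]
    )
    return {"records": records, "counts": counts}


def random_stratified_table(rng, n_strata=30, with_covariate=False):
    """Small random informative-ish stratified table for estimator tests."""
    rows = []
    for s in range(n_strata):
        size = int(rng.integers(4, 6))
        x = (rng.random(size) < 0.3).astype(int)
        alpha = rng.normal(0.5, 0.5)
        z = rng.standard_normal(size)
        eta = alpha + 0.3 * x + (0.1 * z if with_covariate else 0.0)
        y = rng.poisson(np.exp(eta))
        frame = {"stratum_id": f"s{s:04d}", "y": y, "x": x}
        if with_covariate:
            frame["z"] = z
        rows.append(pd.DataFrame(frame))
    return pd.concat(rows, ignore_index=True)
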