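"""Synthetic study frame: gridded weather, regions and overdispersed counts.

The generator emulates the inputs of a warm-season (May-September),
multi-year extreme-heat study at the scale of small postal regions:

* a daily gridded maximum/mean temperature and vapour-pressure field with a
  seasonal cycle, spatially correlated anomalies (exponential covariance),
  AR(1) persistence in time and white measurement noise — persistence is
  what produces the rare multi-day exceedance runs that define extreme heat
  events;
* toy region polygons tiling the grid, each with an inhabited-land
  (ecumene) sub-polygon, some regions deliberately misaligned with cell
  boundaries so pixel-fraction weighting is exercised;
* overdispersed daily event counts whose log-rate is a stratum intercept
  plus a known exposure effect, so the conditional estimator can be tested
  for parameter recovery.  Counts are negative-binomial with variance
  phi * mu (the quasi-Poisson variance assumption, exactly, at the moment
  level); stratum intercepts are drawn Normal(log baseline, 0.5^2), which
  induces the between-stratum confounding the conditional analysis removes.

All randomness derives from one seed expanded into per-component
substreams, so components are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box, mapping, shape

from .spatial import GridGeometry, saturation_vapour_pressure

__all__ = [
    "SimConfig",
    "WeatherGrid",
    "warm_season_calendar",
    "simulate_weather",
    "simulate_regions",
    "simulate_counts",
    "simulate_stratum_counts",
    "recovery_table",
    "negative_binomial_counts",
    "regions_to_geojson",
    "regions_from_geojson",
    "DEFAULT_PROFILES",
]

LEADIN_DAYS = 2  # days before each season start so day-1 exposure and lags exist

_BASE_TEMP_C = 22.0  # season-edge mean daily maximum
_DIURNAL_OFFSET_C = 8.0  # tmax - tmean


@dataclass(frozen=True)
class SimConfig:
    """Study-frame parameters for the synthetic generator.

    Defaults mirror a ten-year May-September frame over a small grid of
    1 km cells with nine regions, strong day-to-day persistence and a
    moderately overdispersed count process with an embedded true rate
    ratio of 1.29.
    """

    n_years: int = 10
    start_year: int = 2005
    months: frozenset[int] = frozenset({5, 6, 7, 8, 9})
    grid_shape: tuple[int, int] = (12, 12)
    cell_size_km: float = 1.0
    n_regions: int = 9
    seasonal_mean_amp: float = 8.0
    spatial_corr_range_km: float = 6.0
    spatial_sd: float = 3.0
    daily_ar1_rho: float = 0.8
    noise_sd: float = 0.4
    burst_rate: float = 2.2  # mean synoptic heat bursts per season
    burst_amp_c: float = 7.0  # mean burst amplitude (degC), grid-wide
    true_log_rr: float = float(np.log(1.29))
    baseline_rate: float = 2.0
    overdispersion: float = 1.5
    seed: int = 20050501

    def __post_init__(self):
        for name in (
            "seasonal_mean_amp",
            "spatial_corr_range_km",
            "spatial_sd",
            "daily_ar1_rho",
            "noise_sd",
            "burst_rate",
            "burst_amp_c",
            "true_log_rr",
            "baseline_rate",
            "overdispersion",
            "cell_size_km",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite SimConfig field: {name}")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not (0.0 <= self.daily_ar1_rho < 1.0):
            raise ValueError("daily_ar1_rho must lie in [0, 1)")
        if self.overdispersion < 1.0:
            raise ValueError(
                "overdispersion must be >= 1 (variance below Poisson is not representable)"
            )
        if not set(self.months) <= set(range(1, 13)):
            raise ValueError("months must be a subset of 1..12")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named independent substreams of the global seed."""
        root = np.random.SeedSequence(self.seed)
        names = ("weather", "regions", "counts", "humidity")
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass(frozen=True)
class WeatherGrid:
    """Daily gridded weather: tmax/tmean (degC), vapour pressure (kPa)."""

    data: xr.Dataset  # dims (date, row, col)
    geometry: GridGeometry

    def __getitem__(self, key):
        return self.data[key]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["date"].values)

    def to_frame(self) -> pd.DataFrame:
        """Long-format CSV fallback (date, row, col, tmax_c, tmean_c, vp_kpa)."""
        df = self.data.to_dataframe().reset_index()
        return df.rename(columns={"tmax": "tmax_c", "tmean": "tmean_c", "vp": "vp_kpa"})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, geometry: GridGeometry) -> "WeatherGrid":
        ds = (
            df.rename(columns={"tmax_c": "tmax", "tmean_c": "tmean", "vp_kpa": "vp"})
            .set_index(["date", "row", "col"])[["tmax", "tmean", "vp"]]
            .to_xarray()
        )
        return cls(data=ds, geometry=geometry)


def warm_season_calendar(config: SimConfig) -> pd.DataFrame:
    """Dates of every simulated day with the ``analysed`` flag.

    Analysed days are all days of the configured warm-season months; each
    season is preceded by lead-in days (``analysed`` False) so that the
    consecutive-day exposure rule and lags are defined from day one.
    """
    months = sorted(config.months)
    frames = []
    for year in range(config.start_year, config.start_year + config.n_years):
        start = pd.Timestamp(year=year, month=months[0], day=1)
        end = pd.Timestamp(year=year, month=months[-1], day=1) + pd.offsets.MonthEnd(0)
        days = pd.date_range(start - pd.Timedelta(days=LEADIN_DAYS), end, freq="D")
        frames.append(
            pd.DataFrame(
                {"date": days, "analysed": [d.month in config.months for d in days]}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _cell_centres_km(config: SimConfig) -> np.ndarray:
    nrows, ncols = config.grid_shape
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    pts = np.column_stack([(cc.ravel() + 0.5), (rr.ravel() + 0.5)])
    return pts * config.cell_size_km


def _spatial_cholesky(config: SimConfig) -> np.ndarray:
    pts = _cell_centres_km(config)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    cov = np.exp(-d / max(config.spatial_corr_range_km, 1e-12))
    cov[np.diag_indices_from(cov)] += 1e-9
    return np.linalg.cholesky(cov)


def _seasonal_mean(dates: pd.DatetimeIndex, config: SimConfig) -> np.ndarray:
    """Half-sine seasonal cycle peaking mid-season, in degC."""
    months = sorted(config.months)
    season_start = pd.to_datetime(
        {"year": dates.year, "month": months[0], "day": 1}
    ).values
    season_end = (
        pd.to_datetime({"year": dates.year, "month": months[-1], "day": 1})
        + pd.offsets.MonthEnd(0)
    ).values
    day = np.timedelta64(1, "D")
    frac = ((dates.values - season_start) / day) / np.maximum(
        (season_end - season_start) / day, 1
    )
    frac = np.clip(frac, 0.0, 1.0)
    return _BASE_TEMP_C + config.seasonal_mean_amp * np.sin(np.pi * frac)


_BURST_LEN = 2  # days per synoptic burst; mirrors the two-day event definition
_BURST_AMP_SD = 2.0
_BURST_ANOMALY_DAMP = 0.35  # heat domes suppress day-to-day variability


def _heat_bursts(rng: np.random.Generator, dates: pd.DatetimeIndex, config: SimConfig) -> np.ndarray:
    """Grid-wide synoptic heat bursts: rare two-day temperature surges.

    Per season the number of bursts is Poisson(burst_rate); each burst
    covers two consecutive mid-season days and lifts the whole grid by
    roughly burst_amp_c.  These are what create the paired exceedance days
    that define extreme heat events — a first-order AR anomaly alone almost
    never places two of its few 99th-percentile days back to back in most
    seasons.
    """
    burst = np.zeros(len(dates))
    if config.burst_rate <= 0 or config.burst_amp_c == 0:
        return burst
    years = dates.year
    for year in np.unique(years):
        idx = np.flatnonzero(years == year)
        n_days = len(idx)
        for _ in range(rng.poisson(config.burst_rate)):
            start = rng.integers(int(0.2 * n_days), int(0.8 * n_days) - _BURST_LEN)
            amp = rng.normal(config.burst_amp_c, _BURST_AMP_SD)
            burst[idx[start : start + _BURST_LEN]] += max(amp, 0.0)
    return burst


def simulate_weather(config: SimConfig) -> WeatherGrid:
    """Simulate the daily gridded weather field.

    tmax = seasonal half-sine + grid-wide heat bursts + spatially correlated
    AR(1) anomaly + white noise; tmean = tmax - a fixed positive diurnal
    offset; vapour pressure is a random fraction (0.35-0.85) of saturation
    at tmean, hence positive and below saturation.  Fixed seed gives
    bit-identical output.
    """
    rng = config.streams()["weather"]
    rng_h = config.streams()["humidity"]
    calendar = warm_season_calendar(config)
    dates = pd.DatetimeIndex(calendar["date"])
    nrows, ncols = config.grid_shape
    ncells = nrows * ncols
    chol = _spatial_cholesky(config)
    rho = config.daily_ar1_rho

    seasonal = _seasonal_mean(dates, config)
    burst = _heat_bursts(rng, dates, config)
    anomalies = np.empty((len(dates), ncells))
    years = dates.year
    prev_year = None
    state = np.zeros(ncells)
    for i, year in enumerate(years):
        z = chol @ rng.standard_normal(ncells)
        if year != prev_year:  # seasons are independent; re-initialise the AR state
            state = config.spatial_sd * z
            prev_year = year
        else:
            state = rho * state + np.sqrt(1.0 - rho**2) * config.spatial_sd * z
        anomalies[i] = state
    noise = config.noise_sd * rng.standard_normal((len(dates), ncells))
    damp = np.where(burst > 0, _BURST_ANOMALY_DAMP, 1.0)
    tmax = (seasonal + burst)[:, None] + damp[:, None] * anomalies + noise
    tmean = tmax - _DIURNAL_OFFSET_C
    rh_frac = rng_h.uniform(0.35, 0.85, size=tmax.shape)
    vp = rh_frac * saturation_vapour_pressure(tmean)

    ds = xr.Dataset(
        {
            "tmax": (("date", "row", "col"), tmax.reshape(len(dates), nrows, ncols)),
            "tmean": (("date", "row", "col"), tmean.reshape(len(dates), nrows, ncols)),
            "vp": (("date", "row", "col"), vp.reshape(len(dates), nrows, ncols)),
        },
        coords={
            "date": dates.values,
            "row": np.arange(nrows),
            "col": np.arange(ncols),
        },
    )
    geometry = GridGeometry(
        x0=0.0,
        y0=0.0,
        dx=config.cell_size_km,
        dy=config.cell_size_km,
        nrows=nrows,
        ncols=ncols,
    )
    return WeatherGrid(data=ds, geometry=geometry)


def simulate_regions(config: SimConfig, grid: WeatherGrid) -> dict[str, dict]:
    """Tile part of the grid into region polygons with ecumene masks.

    Regions are rectangular blocks; the first region is shrunk off the cell
    lattice so its boundary cuts through cells (partial pixel fractions),
    the others stay cell-aligned.  Each ecumene is a rectangular sub-polygon
    covering 30-100% of its region.
    """
    rng = config.streams()["regions"]
    nrows, ncols = config.grid_shape
    k = int(np.ceil(np.sqrt(config.n_regions)))
    bw, bh = ncols // k, nrows // k  # block size in cells
    if bw < 1 or bh < 1 or config.n_regions > k * k:
        raise ValueError(
            f"n_regions={config.n_regions} exceeds the capacity of a "
            f"{nrows}x{ncols} grid"
        )
    cs = config.cell_size_km
    regions: dict[str, dict] = {}
    for i in range(config.n_regions):
        brow, bcol = divmod(i, k)
        x0, y0 = bcol * bw * cs, brow * bh * cs
        x1, y1 = x0 + bw * cs, y0 + bh * cs
        if i == 0 and bw * bh >= 4:
            # misaligned region: boundary cuts through grid cells
            poly = box(x0 + 0.35 * cs, y0 + 0.25 * cs, x1 - 0.45 * cs, y1 - 0.15 * cs)
        else:
            poly = box(x0, y0, x1, y1)
        frac = rng.uniform(0.55, 1.0)  # ecumene area fraction, comfortably in [0.3, 1]
        fx = fy = np.sqrt(frac)
        px0, py0, px1, py1 = poly.bounds
        w, h = px1 - px0, py1 - py0
        anchor = rng.integers(0, 4)
        ex0 = px0 if anchor in (0, 2) else px1 - fx * w
        ey0 = py0 if anchor in (0, 1) else py1 - fy * h
        ecumene = box(ex0, ey0, ex0 + fx * w, ey0 + fy * h)
        regions[f"R{i:02d}"] = {"polygon": poly, "ecumene": ecumene}
    return regions


def regions_to_geojson(regions: dict[str, dict]) -> dict:
    """GeoJSON FeatureCollection; the ecumene rides in feature properties."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(geoms["polygon"]),
                "properties": {
                    "region_id": region_id,
                    "ecumene": mapping(geoms["ecumene"]),
                },
            }
            for region_id, geoms in regions.items()
        ],
    }


def regions_from_geojson(doc: dict) -> dict[str, dict]:
    out = {}
    for feat in doc["features"]:
        props = feat["properties"]
        out[props["region_id"]] = {
            "polygon": shape(feat["geometry"]),
            "ecumene": shape(props["ecumene"]),
        }
    return out


def negative_binomial_counts(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """Counts with mean mu and variance phi*mu (Poisson when phi == 1).

    Negative-binomial (NB2) with size r = mu / (phi - 1) and success
    probability 1/phi has exactly this mean-variance pair.
    """
    if phi < 1.0:
        raise ValueError("phi must be >= 1 (variance below Poisson not representable)")
    mu = np.asarray(mu, dtype=float)
    if phi == 1.0:
        return rng.poisson(mu)
    r = mu / (phi - 1.0)
    return rng.negative_binomial(r, 1.0 / phi)


# event profile: (primary code, secondary codes, probability).  External-cause
# profiles always pair the V/W secondary with an S/T primary, as real abstracts
# do, which keeps falls/transport/drowning subsets of injury in the data.
DEFAULT_PROFILES: tuple[tuple[str, str, float], ...] = (
    ("J06", "", 0.100),  # upper respiratory infection
    ("J45", "", 0.060),  # asthma
    ("J18", "", 0.040),  # pneumonia (lower respiratory)
    ("J21", "", 0.030),  # bronchiolitis (lower respiratory)
    ("A08", "", 0.050),  # viral enteritis (also infectious)
    ("B34", "", 0.030),  # viral infection
    ("N10", "", 0.020),  # pyelonephritis (renal)
    ("N39", "", 0.020),  # urinary tract infection (renal)
    ("H66", "", 0.030),  # otitis media
    ("E86", "", 0.015),  # dehydration (also heat)
    ("T67.0", "", 0.010),  # heatstroke (also heat)
    ("S52", "W10", 0.070),  # forearm fracture, fall from steps
    ("S09", "V18", 0.040),  # head injury, pedal-cycle crash
    ("S06", "V43", 0.030),  # concussion, car occupant
    ("T75.1", "W67", 0.005),  # non-fatal submersion (drowning)
    ("T15", "", 0.030),  # foreign body in eye (injury)
    ("R10", "", 0.120),  # abdominal pain (all-cause only)
    ("R50", "", 0.100),  # fever (all-cause only)
    ("R05", "", 0.100),  # cough (all-cause only)
    ("Z03", "", 0.100),  # observation (all-cause only)
)

_AGE_SPLIT = {"0-4": 0.45, "5-12": 0.25, "13-18": 0.30}
_SEX_SPLIT = {"M": 0.50, "F": 0.47, "": 0.03}  # "" = missing sex


def simulate_stratum_counts(
    rng: np.random.Generator,
    x: np.ndarray,
    stratum_codes: np.ndarray,
    true_log_rr: float,
    baseline_rate: float,
    overdispersion: float,
    alpha_sd: float = 0.5,
) -> np.ndarray:
    """Counts y with log-mean alpha_stratum + beta * x, variance phi*mu.

    ``stratum_codes`` are consecutive integer labels; one intercept
    alpha_s ~ Normal(log baseline, alpha_sd^2) is drawn per stratum.
    """
    n_strata = int(stratum_codes.max()) + 1 if len(stratum_codes) else 0
    alphas = rng.normal(np.log(baseline_rate), alpha_sd, size=n_strata)
    mu = np.exp(alphas[stratum_codes] + true_log_rr * np.asarray(x, dtype=float))
    return negative_binomial_counts(rng, mu, overdispersion)


def recovery_table(
    rng: np.random.Generator,
    n_strata: int = 500,
    true_log_rr: float = float(np.log(1.29)),
    overdispersion: float = 1.5,
    baseline_rate: float = 2.0,
) -> pd.DataFrame:
    """One parameter-recovery replicate in case-crossover geometry.

    Each stratum has 4 or 5 same-weekday days with one exposed day (two in
    20% of strata), a Normal(log baseline, 0.5^2) intercept and
    overdispersed counts with the embedded log rate ratio.  Returns a
    stratified table (stratum_id, y, x) ready for filtering and fitting.
    """
    sizes = rng.integers(4, 6, size=n_strata)
    codes = np.repeat(np.arange(n_strata), sizes)
    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    x = np.zeros(codes.shape, dtype=int)
    for s in range(n_strata):
        k = 1 if rng.random() < 0.8 else 2
        pos = rng.choice(sizes[s], size=k, replace=False)
        x[starts[s] + pos] = 1
    y = simulate_stratum_counts(
        rng, x, codes, true_log_rr, baseline_rate, overdispersion
    )
    return pd.DataFrame({"stratum_id": codes, "y": y, "x": x})


def simulate_counts(
    config: SimConfig,
    exposure: pd.DataFrame,
    strata: pd.Series,
    exposure_def: str = "ehe_p99",
    profiles=DEFAULT_PROFILES,
) -> pd.DataFrame:
    """Generate event records over the analysed region-day frame.

    ``exposure`` is the per-region-day indicator table (module exposure) and
    ``strata`` the matching stratum keys (module design).  Daily all-cause
    totals follow the stratified overdispersed model with the embedded true
    log rate ratio applied through ``exposure_def``; each day's events are
    then split multinomially into diagnostic profiles, age groups and sex
    (a small fraction has missing sex).  Returns the record table in the
    CountTable CSV dialect: date, region_id, icd10_primary, icd10_secondary,
    age_group, sex, count.
    """
    rng = config.streams()["counts"]
    probs = np.array([p for _, _, p in profiles])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"profile probabilities sum to {probs.sum()}, not 1")
    x = exposure[exposure_def].to_numpy()
    codes = pd.factorize(strata, sort=True)[0]
    y = simulate_stratum_counts(
        rng,
        x,
        codes,
        config.true_log_rr,
        config.baseline_rate,
        config.overdispersion,
    )
    # split day totals into profiles, then ages, then sexes
    by_profile = rng.multinomial(y, probs)  # (n_days, n_profiles)
    day_idx, prof_idx = np.nonzero(by_profile)
    cell_counts = by_profile[day_idx, prof_idx]
    age_labels = list(_AGE_SPLIT)
    by_age = rng.multinomial(cell_counts, np.array(list(_AGE_SPLIT.values())))
    rows = []
    sex_labels = list(_SEX_SPLIT)
    sex_p = np.array(list(_SEX_SPLIT.values()))
    for a, age in enumerate(age_labels):
        nz = np.nonzero(by_age[:, a])[0]
        by_sex = rng.multinomial(by_age[nz, a], sex_p)
        for s, sex in enumerate(sex_labels):
            nzs = np.nonzero(by_sex[:, s])[0]
            idx = nz[nzs]
            rows.append(
                pd.DataFrame(
                    {
                        "date": exposure["date"].to_numpy()[day_idx[idx]],
                        "region_id": exposure["region_id"].to_numpy()[day_idx[idx]],
                        "icd10_primary": [profiles[j][0] for j in prof_idx[idx]],
                        "icd10_secondary": [profiles[j][1] for j in prof_idx[idx]],
                        "age_group": age,
                        "sex": sex,
                        "count": by_sex[nzs, s],
                    }
                )
            )
    records = pd.concat(rows, ignore_index=True)
    return records.sort_values(
        ["date", "region_id", "icd10_primary", "age_group", "sex"], ignore_index=True
    )
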