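"""Extreme heat event (EHE) exposure construction.

An EHE day is a day whose maximum temperature exceeds a region-specific
percentile threshold AND whose preceding day also exceeded it — the
"two consecutive days" rule.  Thresholds are the empirical 99th, 97.5th and
95th percentiles of warm-season daily maximum temperature, pooled over all
study years per region (a year-averaged alternative is switchable).  Lagged
indicators mark days 1 or 2 days after an EHE day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdTable",
    "compute_thresholds",
    "ehe_indicator",
    "lag_indicator",
    "build_exposure_series",
    "DEFAULT_PERCENTILES",
    "percentile_column",
]

DEFAULT_PERCENTILES = (99.0, 97.5, 95.0)

MIN_POOLED_DAYS = 100


class ThresholdWarning(UserWarning):
    """Thresholds computed from too few pooled days are unstable."""


@dataclass(frozen=True)
class ThresholdTable:
    """Per-region temperature thresholds (degC), one column per percentile."""

    table: pd.DataFrame  # index region_id, columns like "p99", "p975", "p95"

    def threshold(self, region_id: str, percentile: float) -> float:
        return float(self.table.loc[region_id, percentile_column(percentile)])


def percentile_column(p: float) -> str:
    """Column name for a percentile: 99 -> 'p99', 97.5 -> 'p975'."""
    text = f"{p:g}".replace(".", "")
    return f"p{text}"


def compute_thresholds(
    series: pd.DataFrame,
    percentiles=DEFAULT_PERCENTILES,
    method: str = "pooled",
) -> ThresholdTable:
    """Empirical tmax percentiles per region over analysed warm-season days.

    ``series`` must carry region_id, date, tmax_c and a boolean ``analysed``
    column (lead-in days False); lead-in days never enter the pooling.
    ``method='pooled'`` (default) pools all years into one empirical
    distribution; ``method='by_year'`` averages each year's percentile.
    Linear interpolation between order statistics in both cases.
    """
    if method not in ("pooled", "by_year"):
        raise ValueError(f"unknown percentile method {method!r}")
    percentiles = list(percentiles)
    analysed = series[series["analysed"]] if "analysed" in series else series
    rows = {}
    for region_id, grp in analysed.groupby("region_id", sort=True):
        tmax = grp["tmax_c"].to_numpy(dtype=float)
        if tmax.size < MIN_POOLED_DAYS:
            warnings.warn(
                f"region {region_id!r}: only {tmax.size} pooled days "
                f"(< {MIN_POOLED_DAYS}); thresholds unstable",
                ThresholdWarning,
                stacklevel=2,
            )
        if method == "pooled":
            vals = np.percentile(tmax, percentiles)
        else:
            years = pd.DatetimeIndex(grp["date"]).year
            per_year = [
                np.percentile(tmax[years == y], percentiles) for y in np.unique(years)
            ]
            vals = np.mean(per_year, axis=0)
        rows[region_id] = vals
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[percentile_column(p) for p in percentiles]
    )
    table.index.name = "region_id"
    return ThresholdTable(table=table)


def ehe_indicator(
    tmax: pd.Series, threshold: float, strict_leadin: bool = True
) -> pd.Series:
    """Two-consecutive-day exceedance indicator over a daily tmax series.

    ``tmax`` is indexed by consecutive calendar dates (the lead-in day before
    each analysed day must be present).  ehe(t) = 1 iff tmax(t) > threshold
    and tmax(t-1) > threshold; ties at the threshold are non-exceedances.

    An exceedance whose preceding calendar day is absent cannot be evaluated:
    with ``strict_leadin`` (default) this raises naming the date; with
    ``strict_leadin=False`` such positions are set to 0 (used for the first
    lead-in day of a season block, whose own indicator is only consumed by
    lagged definitions where undefined means unexposed).
    """
    idx = pd.DatetimeIndex(tmax.index)
    if not idx.is_monotonic_increasing:
        raise ValueError("tmax series must be sorted by date")
    exceed = tmax.to_numpy(dtype=float) > threshold
    prev_exists = np.zeros(len(idx), dtype=bool)
    if len(idx) > 1:
        prev_exists[1:] = (idx[1:] - idx[:-1]) == pd.Timedelta(days=1)
    prev_exceed = np.zeros_like(exceed)
    prev_exceed[1:] = exceed[:-1]
    ehe = exceed & prev_exceed & prev_exists
    broken = exceed & ~prev_exists
    if strict_leadin and broken.any():
        date = idx[np.argmax(broken)].date()
        raise ValueError(f"missing preceding day for {date}; supply lead-in days")
    return pd.Series(ehe.astype(np.int8), index=tmax.index)


def lag_indicator(ehe: pd.Series, lag: int) -> pd.Series:
    """Shifted indicator: lagL(t) = ehe(t - L), L in {1, 2}.

    Positions whose lagged date precedes the series (season start) are set
    to 0; within-season gaps in the calendar are not allowed here because
    upstream series are gap-free per season.
    """
    if lag not in (1, 2):
        raise ValueError(f"lag must be 1 or 2, got {lag}")
    idx = pd.DatetimeIndex(ehe.index)
    lagged_dates = idx - pd.Timedelta(days=lag)
    pos = idx.get_indexer(lagged_dates)
    out = np.zeros(len(idx), dtype=np.int8)
    found = pos >= 0
    out[found] = ehe.to_numpy()[pos[found]]
    return pd.Series(out, index=ehe.index)


def _season_blocks(dates: pd.DatetimeIndex) -> list[np.ndarray]:
    """Split a sorted date index into blocks of consecutive days."""
    gaps = np.flatnonzero(np.diff(dates.values) != np.timedelta64(1, "D"))
    return np.split(np.arange(len(dates)), gaps + 1)


def build_exposure_series(
    series: pd.DataFrame,
    thresholds: ThresholdTable,
    percentiles=DEFAULT_PERCENTILES,
    lags=(1, 2),
) -> pd.DataFrame:
    """Per-region-day binary EHE indicators for each percentile and lag.

    ``series`` carries region_id, date, tmax_c and the ``analysed`` flag with
    lead-in days included (they make day-1 exposure and lags well defined but
    are excluded from the returned analysed frame).  EHE runs may span month
    boundaries: exposure is physical, independent of the stratification
    calendar.  Output columns: ehe_p99, ehe_p99_lag1, ... per percentile.
    """
    frames = []
    for region_id, grp in series.groupby("region_id", sort=True):
        grp = grp.sort_values("date")
        tmax = grp.set_index("date")["tmax_c"]
        out = pd.DataFrame(index=tmax.index)
        idx = pd.DatetimeIndex(tmax.index)
        blocks = _season_blocks(idx)
        for p in percentiles:
            thr = thresholds.threshold(region_id, p)
            col = f"ehe_{percentile_column(p)}"
            parts = [
                ehe_indicator(tmax.iloc[b], thr, strict_leadin=False) for b in blocks
            ]
            out[col] = pd.concat(parts)
            for lag in lags:
                out[f"{col}_lag{lag}"] = pd.concat(
                    [lag_indicator(part, lag) for part in parts]
                )
        out = out.loc[grp.set_index("date")["analysed"]]
        out = out.reset_index()
        out.insert(0, "region_id", region_id)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
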