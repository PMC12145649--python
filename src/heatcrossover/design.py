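"""Time-stratified case-crossover design construction.

Every analysed region-day belongs to exactly one stratum keyed by
(region, year, month, ISO day-of-week).  Within a month each weekday occurs
4 or 5 times, so each case day is compared against its 3 or 4 same-weekday
control days in the same month, year and region — referents both before and
after the case day, which avoids the time-trend biases of unidirectional
referent schemes.  Confounders that do not vary week to week (age, sex,
SES, population size) cancel by design, so no population offset is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "build_strata",
    "assemble",
    "filter_informative",
    "ExclusionLog",
    "LinkageError",
]


class LinkageError(ValueError):
    """The (region, date) join across inputs was not lossless."""

    def __init__(self, stage: str, missing: pd.DataFrame):
        self.stage = stage
        self.missing = missing
        keys = ", ".join(
            f"({r.region_id}, {pd.Timestamp(r.date).date()})"
            for r in missing.head(5).itertuples()
        )
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        super().__init__(f"{stage}: {len(missing)} unmatched region-days: {keys}{more}")


def stratum_key(region_id, dates) -> pd.Series:
    """Serialised stratum id 'region|year|month|dow' (ISO weekday, Mon=1)."""
    d = pd.DatetimeIndex(pd.to_datetime(dates))
    rid = pd.Series(region_id).astype(str).reset_index(drop=True)
    parts = (
        rid
        + "|"
        + pd.Series(d.year.astype(str))
        + "|"
        + pd.Series(d.month.astype(str))
        + "|"
        + pd.Series((d.dayofweek + 1).astype(str))
    )
    parts.index = pd.Series(region_id).index
    return parts


def build_strata(calendar: pd.DataFrame) -> pd.DataFrame:
    """Assign each analysed region-day its stratum key.

    ``calendar`` carries region_id and date (warm-season analysed days only).
    Returns a copy with a ``stratum_id`` column; the assignment is a partition
    (each region-day appears in exactly one stratum).
    """
    out = calendar.copy()
    out["date"] = pd.to_datetime(out["date"])
    out["stratum_id"] = stratum_key(out["region_id"], out["date"])
    return out


def _merge_lossless(left: pd.DataFrame, right: pd.DataFrame, stage: str) -> pd.DataFrame:
    merged = left.merge(
        right, on=["region_id", "date"], how="left", indicator=True, validate="one_to_one"
    )
    missing = merged.loc[merged["_merge"] != "both", ["region_id", "date"]]
    if len(missing):
        raise LinkageError(stage, missing)
    return merged.drop(columns="_merge")


def assemble(
    counts: pd.DataFrame,
    exposure: pd.DataFrame,
    weather: pd.DataFrame,
    outcome: str,
    demographic: str,
    exposure_def: str,
) -> pd.DataFrame:
    """Join counts, exposure and weather into one stratified analysis table.

    The join on (region_id, date) must be lossless — every analysed
    region-day present in all three inputs — or a :class:`LinkageError`
    lists the missing keys; region-days are never dropped silently.

    ``outcome`` selects the outcome slice of the count table, ``demographic``
    one of its count columns (e.g. ``count_all``, ``count_F``,
    ``count_age_0_4``), and ``exposure_def`` an indicator column of the
    exposure series (e.g. ``ehe_p99`` or ``ehe_p99_lag1``).  Output columns:
    stratum_id, region_id, date, y, x, rh_pct.
    """
    sub = counts[counts["outcome"] == outcome]
    if sub.empty:
        raise ValueError(f"unknown outcome {outcome!r} in count table")
    if demographic not in sub.columns:
        raise ValueError(f"unknown demographic column {demographic!r}")
    if exposure_def not in exposure.columns:
        raise ValueError(f"unknown exposure definition {exposure_def!r}")
    base = sub[["region_id", "date", demographic]].rename(columns={demographic: "y"})
    base = base.copy()
    base["date"] = pd.to_datetime(base["date"])
    expo = exposure[["region_id", "date", exposure_def]].rename(
        columns={exposure_def: "x"}
    )
    expo = expo.copy()
    expo["date"] = pd.to_datetime(expo["date"])
    wx = weather.loc[
        weather["analysed"] if "analysed" in weather else slice(None),
        ["region_id", "date", "rh_pct"],
    ].copy()
    wx["date"] = pd.to_datetime(wx["date"])
    table = _merge_lossless(base, expo, "counts↔exposure")
    table = _merge_lossless(table, wx, "counts↔weather")
    table = build_strata(table)
    return table[["stratum_id", "region_id", "date", "y", "x", "rh_pct"]]


@dataclass(frozen=True)
class ExclusionLog:
    """Tally of strata removed before conditional fitting."""

    n_strata_in: int
    n_zero_events: int
    n_no_exposure_variation: int
    n_strata_kept: int

    def __str__(self) -> str:
        return (
            f"strata in: {self.n_strata_in}; dropped {self.n_zero_events} with zero "
            f"events and {self.n_no_exposure_variation} without exposure contrast; "
            f"kept {self.n_strata_kept}"
        )


def filter_informative(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop strata that cannot contribute to the conditional likelihood.

    A stratum is uninformative when its total event count is zero or when
    the exposure indicator does not vary within it; such strata contribute a
    constant to the conditional likelihood and only distort the dispersion
    degrees of freedom.  Raises when nothing informative remains.
    """
    g = table.groupby("stratum_id")
    total_y = g["y"].transform("sum")
    x_varies = g["x"].transform("nunique") > 1
    keep = (total_y > 0) & x_varies
    n_in = g.ngroups
    zero = table.loc[total_y == 0, "stratum_id"].nunique()
    novar = table.loc[(total_y > 0) & ~x_varies, "stratum_id"].nunique()
    out = table[keep].copy()
    log = ExclusionLog(
        n_strata_in=n_in,
        n_zero_events=zero,
        n_no_exposure_variation=novar,
        n_strata_kept=out["stratum_id"].nunique(),
    )
    if out.empty:
        raise ValueError(f"no informative strata remain ({log})")
    return out, log
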