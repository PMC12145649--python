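"""End-to-end orchestration: simulate or load, aggregate, fit, report.

One run realises the full analysis matrix of a percentile-threshold
extreme-heat case-crossover study: for every exposure definition
(percentile x lag, plus a humidity-adjusted variant), every outcome and
every demographic slice, the stratified table is assembled, uninformative
strata are dropped, the conditional quasi-Poisson model is fitted and a
rate-ratio row is reported.  A manifest records the config hash, seed and
per-stage row counts so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import assemble, build_strata
from .exposure import (
    DEFAULT_PERCENTILES,
    build_exposure_series,
    compute_thresholds,
    percentile_column,
)
from .model import stratified_analysis
from .outcomes import AGE_GROUPS, SEXES, aggregate_counts, default_taxonomy
from .spatial import build_region_series
from .synthetic import (
    SimConfig,
    simulate_counts,
    simulate_regions,
    simulate_weather,
    warm_season_calendar,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "validate_inputs", "exposure_definitions"]

DEFAULT_SLICES = ("all", "M", "F") + tuple(
    f"age_{a.replace('-', '_')}" for a in AGE_GROUPS
)

_SLICE_COLUMNS = {
    "all": "count_all",
    "M": "count_M",
    "F": "count_F",
    **{f"age_{a.replace('-', '_')}": f"count_age_{a.replace('-', '_')}" for a in AGE_GROUPS},
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    sim: SimConfig = field(default_factory=SimConfig)
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    lags: tuple[int, ...] = (0, 1, 2)
    humidity_adjust: bool = True
    outcomes: tuple[str, ...] = ()  # empty = all taxonomy outcomes
    slices: tuple[str, ...] = DEFAULT_SLICES
    out_dir: str = "heatcrossover_out"
    seed: int | None = None  # overrides sim.seed when set

    def __post_init__(self):
        if not set(self.lags) <= {0, 1, 2}:
            raise ValueError("lags must be a subset of {0, 1, 2}")
        unknown = set(self.slices) - set(_SLICE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown demographic slices: {sorted(unknown)}")

    def resolved_sim(self) -> SimConfig:
        if self.seed is None:
            return self.sim
        return dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = SimConfig(**{
            **doc.get("sim", {}),
            **(
                {"months": frozenset(doc["sim"]["months"])}
                if "months" in doc.get("sim", {})
                else {}
            ),
        })
        kwargs = {k: v for k, v in doc.items() if k != "sim"}
        for key in ("percentiles", "lags", "outcomes", "slices"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(sim=sim, **kwargs)

    def to_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["months"] = sorted(d["sim"]["months"])
        for key in ("percentiles", "lags", "outcomes", "slices"):
            d[key] = list(d[key])
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def exposure_definitions(config: RunConfig) -> list[tuple[str, str, tuple[str, ...]]]:
    """(name, exposure column, covariates) for the analysis matrix.

    The primary definition is the highest percentile at lag 0; sensitivity
    definitions vary the lag (highest percentile only), the percentile
    (lag 0) and, when enabled, add the relative-humidity adjustment to the
    primary definition.
    """
    percentiles = sorted(config.percentiles, reverse=True)
    defs: list[tuple[str, str, tuple[str, ...]]] = []
    primary = percentiles[0]
    pcol = percentile_column(primary)
    if 0 in config.lags:
        defs.append((f"{pcol}_lag0", f"ehe_{pcol}", ()))
        if config.humidity_adjust:
            defs.append((f"{pcol}_lag0_rh", f"ehe_{pcol}", ("rh_pct",)))
    for lag in sorted(set(config.lags) - {0}):
        defs.append((f"{pcol}_lag{lag}", f"ehe_{pcol}_lag{lag}", ()))
    for p in percentiles[1:]:
        if 0 in config.lags:
            col = percentile_column(p)
            defs.append((f"{col}_lag0", f"ehe_{col}", ()))
    return defs


def _sex_missing_mask(records: pd.DataFrame) -> pd.Series:
    return ~records["sex"].isin(SEXES)


def run(config: RunConfig, write: bool = True) -> dict:
    """Execute the full pipeline; returns the result bundle.

    Bundle keys: weather (region-day series), thresholds, exposure, counts,
    reports (DataFrame, one row per outcome x exposure definition x slice),
    manifest.  With ``write`` the CSVs, a text summary and the manifest are
    written under ``config.out_dir``.
    """
    sim = config.resolved_sim()
    taxonomy = default_taxonomy()
    outcome_names = config.outcomes or taxonomy.outcome_names
    stage_counts = {}

    logger.info("simulate: weather grid")
    grid = simulate_weather(sim)
    regions = simulate_regions(sim, grid)
    stage_counts["grid_days"] = int(grid.data.sizes["date"])

    logger.info("aggregate: zonal means over %d regions", len(regions))
    series = build_region_series(grid, regions, grid.geometry)
    calendar = warm_season_calendar(sim)
    series = series.merge(calendar, on="date", how="left")
    stage_counts["region_days"] = len(series)

    thresholds = compute_thresholds(series, config.percentiles)
    exposure = build_exposure_series(
        series, thresholds, config.percentiles, lags=sorted(set(config.lags) - {0}) or (1, 2)
    )
    stage_counts["analysed_region_days"] = len(exposure)

    logger.info("simulate: counts with true RR %.4f", float(np.exp(sim.true_log_rr)))
    strata = build_strata(exposure[["region_id", "date"]])["stratum_id"]
    records = simulate_counts(sim, exposure, strata)
    stage_counts["event_records"] = int(records["count"].sum())

    counts = aggregate_counts(records, taxonomy, exposure[["region_id", "date"]])
    stage_counts["count_rows"] = len(counts)

    weather_for_join = series[series["analysed"]][["region_id", "date", "rh_pct"]]

    reports = []
    for def_name, expo_col, covariates in exposure_definitions(config):
        for outcome in outcome_names:
            tables = {}
            for slice_name in config.slices:
                tables[slice_name] = assemble(
                    counts,
                    exposure,
                    weather_for_join,
                    outcome,
                    _SLICE_COLUMNS[slice_name],
                    expo_col,
                )
            reports.extend(
                stratified_analysis(
                    tables, outcome=outcome, exposure_def=def_name, covariates=covariates
                )
            )
    report_df = pd.DataFrame([r.to_row() for r in reports])
    stage_counts["report_rows"] = len(report_df)

    manifest = {
        "config_hash": config.content_hash(),
        "seed": sim.seed,
        "version": __version__,
        "stage_counts": stage_counts,
        "true_rr": float(np.exp(sim.true_log_rr)),
    }
    bundle = {
        "weather": series,
        "thresholds": thresholds,
        "exposure": exposure,
        "counts": counts,
        "records": records,
        "reports": report_df,
        "report_objects": reports,
        "manifest": manifest,
    }
    if write:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["weather"].to_csv(out / "region_daily_series.csv", index=False)
    bundle["thresholds"].table.to_csv(out / "thresholds.csv")
    bundle["exposure"].to_csv(out / "exposure_series.csv", index=False)
    bundle["counts"].to_csv(out / "count_table.csv", index=False)
    bundle["records"].to_csv(out / "event_records.csv", index=False)
    bundle["reports"].to_csv(out / "rr_report.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
    lines = ["rate ratios (percent change, 95% CI)", "=" * 40]
    for r in bundle["report_objects"]:
        if r.slice != "all" or r.error:
            continue
        flag = " [suppressed]" if r.suppressed else ""
        lines.append(f"{r.exposure_def:>14}  {r.outcome:<22} {r.format_abstract()}{flag}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def validate_inputs(paths: dict[str, str]) -> dict:
    """Schema and consistency checks on input files; never raises.

    ``paths`` may name counts_csv, exposure_csv and weather_csv.  Returns
    {"passed": bool, "findings": [...]} with one itemised finding per check.
    """
    findings = []

    def check(ok: bool, message: str):
        findings.append({"ok": bool(ok), "message": message})

    frames = {}
    for key, required in (
        ("counts_csv", ["date", "region_id", "icd10_primary", "icd10_secondary", "age_group", "sex", "count"]),
        ("exposure_csv", ["region_id", "date"]),
        ("weather_csv", ["region_id", "date", "tmax_c", "tmean_c", "vp_kpa"]),
    ):
        path = paths.get(key)
        if path is None:
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # unreadable file is a finding, not a crash
            check(False, f"{key}: unreadable ({exc})")
            continue
        frames[key] = df
        missing = [c for c in required if c not in df.columns]
        check(not missing, f"{key}: required columns present (missing: {missing})")
        if "date" in df.columns:
            parsed = pd.to_datetime(df["date"], errors="coerce")
            check(parsed.notna().all(), f"{key}: all dates parseable ISO-8601")

    if "counts_csv" in frames and "exposure_csv" in frames:
        c, e = frames["counts_csv"], frames["exposure_csv"]
        if "date" in c and "date" in e:
            overlap = len(
                set(pd.to_datetime(c["date"], errors="coerce").dropna())
                & set(pd.to_datetime(e["date"], errors="coerce").dropna())
            )
            check(overlap > 0, f"counts/exposure calendars overlap (shared days: {overlap})")
        if "region_id" in c and "region_id" in e:
            shared = set(c["region_id"]) & set(e["region_id"])
            check(bool(shared), f"counts/exposure regions overlap (shared: {len(shared)})")

    return {"passed": all(f["ok"] for f in findings), "findings": findings}
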