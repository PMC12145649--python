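"""ICD-10 outcome classification and daily count aggregation.

Outcomes are defined by ICD-10 code ranges over 3-character categories
(letter + two digits); a bare code such as ``T67`` covers all of its
subcodes (T67.0–T67.9).  Ranges may cross letters ("S00-T66" includes T00)
and are resolved lexicographically.  Most outcomes match on the primary
diagnosis only; external causes (drownings, falls, transportation) are also
looked up in secondary diagnosis fields, where such codes are recorded.
One record can contribute to several outcomes (J45 is both asthma and
respiratory), and every record counts toward all-cause.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "CodeRange",
    "OutcomeTaxonomy",
    "default_taxonomy",
    "parse_range",
    "normalise_code",
    "classify",
    "aggregate_counts",
    "AGE_GROUPS",
    "SEXES",
]

logger = logging.getLogger(__name__)

AGE_GROUPS = ("0-4", "5-12", "13-18")
SEXES = ("M", "F")

_CODE_RE = re.compile(r"^[A-Z]\d{2}\w*$")
_RANGE_RE = re.compile(r"^([A-Z]\d{2})\s*-\s*([A-Z]?\d{2})$")


def normalise_code(code: str) -> str:
    """Uppercase, strip dots/whitespace: 't67.0' -> 'T670'."""
    return str(code).strip().upper().replace(".", "")


def _category(code: str) -> str:
    """First three characters (letter + 2 digits) of a normalised code."""
    norm = normalise_code(code)
    if not _CODE_RE.match(norm):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return norm[:3]


@dataclass(frozen=True, order=True)
class CodeRange:
    """Closed interval of 3-character ICD-10 categories.

    A single category interval ("T67", i.e. start == end) covers the category
    and every subcode under it.
    """

    start: str  # e.g. "S00"
    end: str  # e.g. "T66"; start <= end lexicographically

    def __contains__(self, code: str) -> bool:
        try:
            cat = _category(code)
        except ValueError:
            return False
        return self.start <= cat <= self.end


def parse_range(text: str) -> CodeRange:
    """Parse range notation: 'J45', 'W00-W19', 'T68-88' (end inherits letter).

    Raises ValueError with the offending token on malformed input.
    """
    token = str(text).strip().upper()
    if re.fullmatch(r"[A-Z]\d{2}", token):
        return CodeRange(start=token, end=token)
    m = _RANGE_RE.match(token)
    if not m:
        raise ValueError(f"malformed ICD-10 range: {text!r}")
    start, end = m.group(1), m.group(2)
    if not end[0].isalpha():
        end = start[0] + end  # "T68-88" -> T68-T88
    if not (start[0] <= end[0] and start <= end):
        raise ValueError(f"descending ICD-10 range: {text!r}")
    return CodeRange(start=start, end=end)


@dataclass(frozen=True)
class OutcomeTaxonomy:
    """Outcome name -> code ranges + field rule.

    ``field_rule`` is ``primary_only`` or ``primary_or_secondary`` per
    outcome.  The all-cause outcome has an empty range list and matches every
    record.
    """

    ranges: dict[str, tuple[CodeRange, ...]]
    field_rules: dict[str, str]

    def __post_init__(self):
        for name, rule in self.field_rules.items():
            if rule not in ("primary_only", "primary_or_secondary"):
                raise ValueError(f"outcome {name!r}: unknown field rule {rule!r}")

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(self.ranges)

    @classmethod
    def from_dict(cls, doc: dict) -> "OutcomeTaxonomy":
        ranges, rules = {}, {}
        for name, entry in doc["outcomes"].items():
            ranges[name] = tuple(parse_range(t) for t in entry.get("ranges", []))
            rules[name] = entry.get("field_rule", "primary_only")
        return cls(ranges=ranges, field_rules=rules)

    @classmethod
    def from_yaml(cls, path) -> "OutcomeTaxonomy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "outcomes": {
                name: {
                    "ranges": [
                        rng.start if rng.start == rng.end else f"{rng.start}-{rng.end}"
                        for rng in self.ranges[name]
                    ],
                    "field_rule": self.field_rules[name],
                }
                for name in self.ranges
            }
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_taxonomy() -> OutcomeTaxonomy:
    """The bundled 15-outcome taxonomy (all-cause + 14 coded outcomes)."""
    ref = resources.files("heatcrossover.data").joinpath("icd10_outcomes.yaml")
    with ref.open() as fh:
        return OutcomeTaxonomy.from_dict(yaml.safe_load(fh))


def classify(
    primary_code: str,
    secondary_codes,
    taxonomy: OutcomeTaxonomy,
) -> set[str]:
    """Outcome names a record contributes to.

    Primary-only outcomes match the primary diagnosis; primary-or-secondary
    outcomes match the primary or any secondary diagnosis.  Unmatched records
    fall into all-cause only.  Order of secondary codes is irrelevant.
    """
    secondary = list(secondary_codes or [])
    out = set()
    for name, ranges in taxonomy.ranges.items():
        if not ranges:  # all-cause
            out.add(name)
            continue
        fields = [primary_code]
        if taxonomy.field_rules[name] == "primary_or_secondary":
            fields += secondary
        if any(code in rng for rng in ranges for code in fields):
            out.add(name)
    return out


def _parse_secondary_field(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return []
    return [tok for tok in str(value).split(";") if tok.strip()]


def aggregate_counts(
    records: pd.DataFrame,
    taxonomy: OutcomeTaxonomy,
    calendar: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-tabulate event records into daily per-region outcome counts.

    ``records`` columns: date, region_id, icd10_primary, icd10_secondary
    (semicolon-delimited), age_group, sex, count.  ``calendar`` carries the
    analysed (region_id, date) frame; records outside it are dropped with a
    logged tally.  The output is the full cross of calendar × outcome with
    explicit zero rows (zeros are informative in count regression), columns
    per demographic slice: count_all plus count_<sex>/count_age_<group>, and
    count_sex_missing.  Sex-missing records enter only the unstratified
    count (count_all) and the age columns.
    """
    cal = calendar[["region_id", "date"]].drop_duplicates().copy()
    cal["date"] = pd.to_datetime(cal["date"])
    records = records.copy()
    records["date"] = pd.to_datetime(records["date"])
    in_frame = records.merge(cal.assign(_keep=True), on=["region_id", "date"], how="left")
    dropped = int(in_frame.loc[in_frame["_keep"].isna(), "count"].sum())
    if dropped:
        logger.info("aggregate_counts: dropped %d events outside the analysed frame", dropped)
    records = in_frame[in_frame["_keep"].notna()].drop(columns="_keep")

    # classify each distinct (primary, secondary) pair once
    pairs = records[["icd10_primary", "icd10_secondary"]].drop_duplicates()
    mapping = {
        (row.icd10_primary, row.icd10_secondary): classify(
            row.icd10_primary, _parse_secondary_field(row.icd10_secondary), taxonomy
        )
        for row in pairs.itertuples()
    }

    slices = (
        [("count_all", lambda df: df)]
        + [
            (f"count_{sex}", lambda df, s=sex: df[df["sex"] == s])
            for sex in SEXES
        ]
        + [("count_sex_missing", lambda df: df[~df["sex"].isin(SEXES)])]
        + [
            (f"count_age_{ag.replace('-', '_')}", lambda df, a=ag: df[df["age_group"] == a])
            for ag in AGE_GROUPS
        ]
    )

    pieces = []
    for outcome in taxonomy.outcome_names:
        keys = [k for k, names in mapping.items() if outcome in names]
        sub = records[
            records.set_index(["icd10_primary", "icd10_secondary"]).index.isin(keys)
        ]
        agg = None
        for col, select in slices:
            part = (
                select(sub)
                .groupby(["region_id", "date"], sort=False)["count"]
                .sum()
                .rename(col)
            )
            agg = part.to_frame() if agg is None else agg.join(part, how="outer")
        if agg is None:
            agg = pd.DataFrame(columns=[c for c, _ in slices])
        agg = cal.set_index(["region_id", "date"]).join(agg, how="left")
        for col, _ in slices:
            agg[col] = (
                pd.to_numeric(agg[col], errors="coerce").fillna(0).astype(int)
            )
        agg = agg.reset_index()
        agg.insert(2, "outcome", outcome)
        pieces.append(agg)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["outcome", "region_id", "date"], ignore_index=True)
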