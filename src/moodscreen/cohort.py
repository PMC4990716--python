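"""Cohort tables: daily mental-health ratings and biweekly PHQ-9 outcomes.

Two tables drive the whole pipeline:

* **daily ratings** — one row per (patient, day, item) with an integer score.
  Items are ``sleep`` (dissatisfaction, 0–10; higher = worse), ``mood``
  (0–7) and ``anxiety`` (0–10).  Sleep is *stored* on the dissatisfaction
  scale so that all three items increase with depression severity; if the
  raw export carries sleep satisfaction, pass ``raw_sleep_is_satisfaction``
  to :func:`read_daily_ratings` and the score is reversed (``10 − raw``)
  exactly once, at ingest.
* **PHQ-9 outcomes** — one row per (patient, test date) with the 0–27 total
  score and the derived binary ``depressed`` label (score ≥ cutoff,
  default 5).

Dates are calendar dates (ISO-8601 in files, normalized ``datetime64`` in
memory); the app collects at day granularity and allows back-filling, so
``report_date >= target_date`` always.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

ITEMS = ("sleep", "mood", "anxiety")
ITEM_RANGES: dict[str, tuple[int, int]] = {
    "sleep": (0, 10),
    "mood": (0, 7),
    "anxiety": (0, 10),
}
PHQ9_RANGE = (0, 27)
DEFAULT_DEPRESSION_CUTOFF = 5

RATING_COLUMNS = ["patient_id", "target_date", "report_date", "item", "score"]
PHQ9_COLUMNS = ["patient_id", "test_date", "score"]
INDICATOR_COLUMNS = [
    "patient_id", "window_end", "approach", "sleep", "mood", "anxiety",
    "n_sleep", "n_mood", "n_anxiety", "depressed",
]
ADHERENCE_COLUMNS = [
    "patient_id", "activeness", "timeliness", "duration", "persistence", "cluster",
]

_DATE_COLUMNS = ("target_date", "report_date", "test_date", "window_end")


class ValidationError(ValueError):
    """A cohort table violates its schema; the message names row and field."""


def reverse_sleep(score):
    """Map sleep satisfaction to dissatisfaction (and back): ``10 − score``."""
    return 10 - score


def _parse_dates(df: pd.DataFrame, columns, *, source: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            i = int(bad.idxmax())
            raise ValidationError(
                f"{source}: row {i}: field '{col}' has unparseable date "
                f"{df[col].iloc[i]!r} (expected ISO-8601)"
            )
        if parsed.isna().any():
            i = int(parsed.isna().idxmax())
            raise ValidationError(f"{source}: row {i}: field '{col}' is missing")
        df[col] = parsed.dt.normalize()
    return df


def _require_columns(df: pd.DataFrame, columns, *, source: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing column(s) {missing}")


def validate_ratings(df: pd.DataFrame, *, source: str = "daily ratings") -> pd.DataFrame:
    """Validate a ratings table already in memory; returns a clean copy."""
    _require_columns(df, RATING_COLUMNS, source=source)
    df = df[RATING_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df = _parse_dates(df, ("target_date", "report_date"), source=source)

    bad_item = ~df["item"].isin(ITEMS)
    if bad_item.any():
        i = int(bad_item.idxmax())
        raise ValidationError(
            f"{source}: row {i}: field 'item' has unknown value "
            f"{df['item'].iloc[i]!r} (expected one of {ITEMS})"
        )

    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any() or (scores != scores.round()).any():
        mask = scores.isna() | (scores != scores.round())
        i = int(mask.idxmax())
        raise ValidationError(
            f"{source}: row {i}: field 'score' is not an integer "
            f"({df['score'].iloc[i]!r})"
        )
    df["score"] = scores.astype(int)

    for item, (lo, hi) in ITEM_RANGES.items():
        mask = (df["item"] == item) & ~df["score"].between(lo, hi)
        if mask.any():
            i = int(mask.idxmax())
            raise ValidationError(
                f"{source}: row {i}: field 'score' value {df['score'].iloc[i]} "
                f"out of range [{lo},{hi}] for item '{item}'"
            )

    future = df["report_date"] < df["target_date"]
    if future.any():
        i = int(future.idxmax())
        raise ValidationError(
            f"{source}: row {i}: field 'report_date' "
            f"({df['report_date'].iloc[i].date()}) precedes target_date "
            f"({df['target_date'].iloc[i].date()})"
        )

    dup = df.duplicated(subset=["patient_id", "target_date", "item"], keep=False)
    if dup.any():
        i = int(df.index[dup][1])
        row = df.loc[i]
        raise ValidationError(
            f"{source}: row {i}: duplicate rating for "
            f"(patient {row['patient_id']}, {row['target_date'].date()}, {row['item']})"
        )
    return df.reset_index(drop=True)


def read_daily_ratings(path, raw_sleep_is_satisfaction: bool = False) -> pd.DataFrame:
    """Read and validate the daily-ratings CSV.

    Parameters
    ----------
    path : path-like
        CSV with header ``patient_id,target_date,report_date,item,score``.
    raw_sleep_is_satisfaction : bool
        If the file stores sleep *satisfaction* (0 very bad … 10 very good),
        reverse it on ingest so sleep is stored as dissatisfaction.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "item": str})
    df = validate_ratings(df, source=str(path))
    if raw_sleep_is_satisfaction:
        sleep = df["item"] == "sleep"
        df.loc[sleep, "score"] = reverse_sleep(df.loc[sleep, "score"])
    return df


def validate_phq9(
    df: pd.DataFrame,
    depression_cutoff: int = DEFAULT_DEPRESSION_CUTOFF,
    *,
    source: str = "phq9",
) -> pd.DataFrame:
    _require_columns(df, PHQ9_COLUMNS, source=source)
    df = df[PHQ9_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df = _parse_dates(df, ("test_date",), source=source)

    scores = pd.to_numeric(df["score"], errors="coerce")
    lo, hi = PHQ9_RANGE
    bad = scores.isna() | (scores != scores.round()) | ~scores.between(lo, hi)
    if bad.any():
        i = int(bad.idxmax())
        raise ValidationError(
            f"{source}: row {i}: field 'score' value {df['score'].iloc[i]!r} "
            f"not an integer in [{lo},{hi}]"
        )
    df["score"] = scores.astype(int)

    dup = df.duplicated(subset=["patient_id", "test_date"], keep=False)
    if dup.any():
        i = int(df.index[dup][1])
        row = df.loc[i]
        raise ValidationError(
            f"{source}: row {i}: duplicate PHQ-9 for "
            f"(patient {row['patient_id']}, {row['test_date'].date()})"
        )
    df["depressed"] = (df["score"] >= depression_cutoff).astype(int)
    return df.reset_index(drop=True)


def read_phq9(path, depression_cutoff: int = DEFAULT_DEPRESSION_CUTOFF) -> pd.DataFrame:
    """Read the biweekly PHQ-9 CSV; ``depressed = 1`` iff score ≥ cutoff."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    return validate_phq9(df, depression_cutoff, source=str(path))


@dataclass
class CohortTables:
    """A validated cohort: daily ratings plus biweekly PHQ-9 outcomes."""

    ratings: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        rated = set(self.ratings["patient_id"])
        tested = set(self.outcomes["patient_id"])
        orphans = tested - rated
        if orphans:
            logger.warning(
                "%d patient(s) have PHQ-9 tests but no daily ratings: %s",
                len(orphans), sorted(orphans)[:10],
            )
        unlabelled = rated - tested
        if unlabelled:
            # mirrors the study's exclusion of patients with no PHQ-9 result
            logger.info(
                "%d patient(s) have ratings but no PHQ-9 test and will not "
                "enter the screening model", len(unlabelled),
            )

    @classmethod
    def from_files(
        cls,
        ratings_path,
        phq9_path,
        raw_sleep_is_satisfaction: bool = False,
        depression_cutoff: int = DEFAULT_DEPRESSION_CUTOFF,
    ) -> "CohortTables":
        return cls(
            ratings=read_daily_ratings(ratings_path, raw_sleep_is_satisfaction),
            outcomes=read_phq9(phq9_path, depression_cutoff),
        )

    @property
    def n_patients(self) -> int:
        return self.outcomes["patient_id"].nunique()


def write_table(table: pd.DataFrame, path) -> None:
    """Write a pipeline table as CSV with deterministic layout.

    Column order follows the known schema when the table matches one of the
    pipeline schemas, dates are ISO-8601 and floats use a fixed 12-digit
    general format, so repeated writes are byte-identical.
    """
    df = table.copy()
    for schema in (RATING_COLUMNS, PHQ9_COLUMNS + ["depressed"], PHQ9_COLUMNS,
                   INDICATOR_COLUMNS, ADHERENCE_COLUMNS):
        if set(schema) == set(df.columns):
            df = df[schema]
            break
    for col in df.columns:
        if col in _DATE_COLUMNS and pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
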