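"""Biweekly indicator variables from daily ratings.

Each PHQ-9 test on date *t* defines a window of the 14 days ending on and
including *t*.  Daily ratings falling in the window are collapsed into one
predictor per item by one of three approaches:

* **average** — arithmetic mean of the reported raw scores;
* **frequency** — number of reported days whose score exceeds the item's
  dichotomization cutoff ("depressed days");
* **ratio** — depressed days divided by reported days.

Dichotomization is strict: a day counts as depressed iff ``score > cutoff``.
Windows in which any item has zero reported days are dropped from the
modelling table (ratio and average are undefined on empty sets; uniform
exclusion keeps the three approaches comparable on identical observations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ITEM_RANGES, ITEMS, CohortTables

logger = logging.getLogger(__name__)

APPROACHES = ("ratio", "average", "frequency")
DEFAULT_WINDOW_LEN = 14


@dataclass(frozen=True)
class CutoffSet:
    """Per-item dichotomization cutoffs (a day is depressed iff score > cutoff)."""

    sleep: int
    mood: int
    anxiety: int

    def __post_init__(self) -> None:
        for item in ITEMS:
            lo, hi = ITEM_RANGES[item]
            v = getattr(self, item)
            if not lo <= v <= hi:
                raise ValueError(f"{item} cutoff {v} outside scale [{lo},{hi}]")

    def __getitem__(self, item: str) -> int:
        return getattr(self, item)


def dichotomize_day(score: int, cutoff: int) -> int:
    """1 iff the day's score is strictly above the cutoff."""
    return int(score > cutoff)


def build_ratio(binary_days) -> float:
    """Depressed days / reported days; NaN when nothing was reported."""
    b = np.asarray(binary_days, dtype=float)
    return float(b.mean()) if b.size else float("nan")


def build_frequency(binary_days) -> int:
    """Count of depressed days among reported days."""
    b = np.asarray(binary_days, dtype=float)
    return int(b.sum()) if b.size else 0


def build_average(scores) -> float:
    """Mean raw score over reported days; NaN when nothing was reported."""
    s = np.asarray(scores, dtype=float)
    return float(s.mean()) if s.size else float("nan")


def assign_windows(
    ratings: pd.DataFrame,
    outcomes: pd.DataFrame,
    window_len: int = DEFAULT_WINDOW_LEN,
    exclude_same_day: bool = False,
) -> pd.DataFrame:
    """Attach each daily rating to the PHQ-9 window it informs.

    A rating with target date *d* belongs to the window of the PHQ-9 taken
    on *t* iff ``t − (window_len − 1) <= d <= t``.  When two tests of one
    patient are closer than ``window_len`` days the rating goes to the
    earliest eligible window only (warned, since it indicates an irregular
    schedule).  ``exclude_same_day`` drops ratings with ``d == t`` — the
    robustness subsample guarding against same-day cross-contamination.

    Returns the ratings table augmented with a ``window_end`` column,
    restricted to ratings that fall inside some window.
    """
    r = ratings.sort_values(["target_date", "patient_id"]).reset_index(drop=True)
    o = outcomes.sort_values(["test_date", "patient_id"]).reset_index(drop=True)

    gap = (o.sort_values(["patient_id", "test_date"])
             .groupby("patient_id")["test_date"].diff().dt.days)
    if (gap < window_len).any():
        logger.warning(
            "PHQ-9 tests closer than %d days for %d patient pair(s); each "
            "rating is assigned to the earliest eligible window only",
            window_len, int((gap < window_len).sum()),
        )

    merged = pd.merge_asof(
        r, o[["patient_id", "test_date"]].rename(columns={"test_date": "window_end"}),
        left_on="target_date", right_on="window_end",
        by="patient_id", direction="forward",
        tolerance=pd.Timedelta(days=window_len - 1),
    )
    merged = merged.dropna(subset=["window_end"])
    if exclude_same_day:
        merged = merged[merged["target_date"] != merged["window_end"]]
    return merged.reset_index(drop=True)


def indicators_from_windowed(
    windowed: pd.DataFrame,
    outcomes: pd.DataFrame,
    approach: str,
    cutoffs: CutoffSet | None = None,
    window_len: int = DEFAULT_WINDOW_LEN,
) -> pd.DataFrame:
    """Collapse window-assigned ratings into the modelling table.

    ``windowed`` is the output of :func:`assign_windows` (possibly
    restricted, e.g. to cross-validation training windows).
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected {APPROACHES}")
    if approach in ("ratio", "frequency") and cutoffs is None:
        raise ValueError(f"the {approach} approach requires a CutoffSet")

    w = windowed.copy()
    if approach == "average":
        w["value"] = w["score"].astype(float)
        agg = "mean"
    else:
        cut = w["item"].map({item: cutoffs[item] for item in ITEMS})
        w["value"] = (w["score"] > cut).astype(float)
        agg = "mean" if approach == "ratio" else "sum"

    grouped = (w.groupby(["patient_id", "window_end", "item"])["value"]
                 .agg(value=agg, n="size").reset_index())
    wide = grouped.pivot(index=["patient_id", "window_end"], columns="item")
    values = wide["value"].reindex(columns=list(ITEMS))
    counts = wide["n"].reindex(columns=list(ITEMS))

    complete = values.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "dropping %d window(s) with zero reported days for at least one item",
            n_dropped,
        )
    values = values[complete]
    counts = counts[complete].astype(int)

    table = values.reset_index()[["patient_id", "window_end"] + list(ITEMS)]
    if approach == "frequency":
        table[list(ITEMS)] = table[list(ITEMS)].astype(int)
    for item in ITEMS:
        table[f"n_{item}"] = counts.reset_index()[item].to_numpy()
    table = table.merge(
        outcomes[["patient_id", "test_date", "depressed"]].rename(
            columns={"test_date": "window_end"}),
        on=["patient_id", "window_end"], how="inner",
    )
    table.insert(2, "approach", approach)
    return table.sort_values(["patient_id", "window_end"]).reset_index(drop=True)


def build_indicator_table(
    cohort: CohortTables,
    approach: str,
    cutoffs: CutoffSet | None = None,
    window_len: int = DEFAULT_WINDOW_LEN,
    exclude_same_day: bool = False,
) -> pd.DataFrame:
    """One row per (patient, PHQ-9 window): the three item indicators,
    per-item reported-day counts, and the binary depressed outcome."""
    windowed = assign_windows(cohort.ratings, cohort.outcomes,
                              window_len, exclude_same_day)
    if windowed.empty:
        cols = (["patient_id", "window_end", "approach"] + list(ITEMS)
                + [f"n_{i}" for i in ITEMS] + ["depressed"])
        return pd.DataFrame(columns=cols)
    return indicators_from_windowed(windowed, cohort.outcomes, approach,
                                    cutoffs, window_len)
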