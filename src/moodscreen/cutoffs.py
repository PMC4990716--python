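"""AUC-maximizing dichotomization cutoffs, one rating item at a time.

The ratio and frequency approaches need a per-item threshold above which a
day counts as depressed.  The search enumerates every integer candidate on
the item's scale (1..scale maximum: the maximum makes every day normal
under the strict inequality; 0 would make nearly every sleep/anxiety day
depressed, and excluding it matches a 10-candidate grid for a 0–10 scale).
Each candidate is scored by rebuilding that item's indicator, fitting a
single-predictor random-intercept logistic model, and computing the AUC of
its predicted probabilities; the candidate with the highest AUC wins, ties
going to the smaller (more sensitive) cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ITEM_RANGES, ITEMS, CohortTables
from .indicators import (
    DEFAULT_WINDOW_LEN,
    CutoffSet,
    assign_windows,
)
from .relogit import PanelDesign, fit_relogit, predict_prob
from .roc import auc_mw

logger = logging.getLogger(__name__)


@dataclass
class CutoffSearchResult:
    item: str
    approach: str
    auc_by_cutoff: dict[int, float]
    best_cutoff: int
    best_auc: float


@dataclass
class CutoffSearch:
    """Per-item search results plus the assembled cutoff triple."""

    results: dict[str, CutoffSearchResult]
    cutoffs: CutoffSet

    def to_dict(self) -> dict:
        return {
            item: {
                "candidates": list(r.auc_by_cutoff),
                "aucs": [float(a) for a in r.auc_by_cutoff.values()],
                "best": r.best_cutoff,
                "best_auc": float(r.best_auc),
            }
            for item, r in self.results.items()
        }


def candidate_cutoffs(item: str) -> list[int]:
    """Integer candidates 1..scale maximum (10 for sleep/anxiety, 7 for mood)."""
    if item not in ITEM_RANGES:
        raise ValueError(f"unknown item {item!r}; expected one of {ITEMS}")
    return list(range(1, ITEM_RANGES[item][1] + 1))


def _item_indicator(windowed: pd.DataFrame, item: str, approach: str,
                    cutoff: int) -> pd.DataFrame:
    w = windowed[windowed["item"] == item]
    flag = (w["score"] > cutoff).astype(float)
    agg = flag.groupby([w["patient_id"], w["window_end"]]).agg(
        ["mean", "sum"])
    value = agg["mean"] if approach == "ratio" else agg["sum"]
    return value.rename("value").reset_index()


def optimize_cutoff_windowed(
    windowed: pd.DataFrame,
    outcomes: pd.DataFrame,
    item: str,
    approach: str,
    quad_points: int = 15,
) -> CutoffSearchResult:
    """Cutoff search on window-assigned ratings (CV-safe entry point)."""
    if approach not in ("ratio", "frequency"):
        raise ValueError("cutoff search applies to the ratio and frequency "
                         f"approaches only, not {approach!r}")
    aucs: dict[int, float] = {}
    best_cutoff, best_auc = None, -np.inf
    outcome_cols = outcomes[["patient_id", "test_date", "depressed"]].rename(
        columns={"test_date": "window_end"})
    for cutoff in candidate_cutoffs(item):
        tab = _item_indicator(windowed, item, approach, cutoff)
        tab = tab.merge(outcome_cols, on=["patient_id", "window_end"], how="inner")
        if tab["value"].nunique() <= 1 or tab["depressed"].nunique() <= 1:
            auc = 0.5  # uninformative candidate: constant predictor or one class
        else:
            design = PanelDesign(
                y=tab["depressed"].to_numpy(float),
                X=np.column_stack([np.ones(len(tab)), tab["value"].to_numpy(float)]),
                groups=tab["patient_id"].to_numpy(),
                names=["const", item],
            )
            fit = fit_relogit(design, quad_points=quad_points)
            auc = auc_mw(predict_prob(fit, design.X),
                         tab["depressed"].to_numpy()).auc
        aucs[cutoff] = auc
        if auc > best_auc + 1e-12:   # strict improvement: ties keep the smaller cutoff
            best_cutoff, best_auc = cutoff, auc
    if all(abs(a - 0.5) < 1e-12 for a in aucs.values()):
        logger.warning("item %s: every candidate is uninformative (AUC 0.5)", item)
    return CutoffSearchResult(item=item, approach=approach, auc_by_cutoff=aucs,
                              best_cutoff=int(best_cutoff), best_auc=float(best_auc))


def optimize_all_windowed(
    windowed: pd.DataFrame,
    outcomes: pd.DataFrame,
    approach: str,
    window_len: int = DEFAULT_WINDOW_LEN,
    quad_points: int = 15,
) -> CutoffSearch:
    results = {
        item: optimize_cutoff_windowed(windowed, outcomes, item, approach,
                                       quad_points)
        for item in ITEMS
    }
    if all(abs(a - 0.5) < 1e-12
           for r in results.values() for a in r.auc_by_cutoff.values()):
        raise ValueError("every candidate cutoff is degenerate for every item "
                         "(constant indicators); cannot choose cutoffs")
    cutoffs = CutoffSet(**{item: r.best_cutoff for item, r in results.items()})
    return CutoffSearch(results=results, cutoffs=cutoffs)


def optimize_cutoff(cohort: CohortTables, item: str, approach: str,
                    window_len: int = DEFAULT_WINDOW_LEN,
                    exclude_same_day: bool = False,
                    quad_points: int = 15) -> CutoffSearchResult:
    """Search the optimal cutoff for one item on a full cohort."""
    windowed = assign_windows(cohort.ratings, cohort.outcomes,
                              window_len, exclude_same_day)
    return optimize_cutoff_windowed(windowed, cohort.outcomes, item, approach,
                                    quad_points)


def optimize_all(cohort: CohortTables, approach: str,
                 window_len: int = DEFAULT_WINDOW_LEN,
                 exclude_same_day: bool = False,
                 quad_points: int = 15) -> CutoffSearch:
    """Independent per-item searches; returns the assembled CutoffSet."""
    windowed = assign_windows(cohort.ratings, cohort.outcomes,
                              window_len, exclude_same_day)
    return optimize_all_windowed(windowed, cohort.outcomes, approach,
                                 window_len, quad_points)
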