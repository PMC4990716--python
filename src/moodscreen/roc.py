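"""ROC curves, tie-aware AUC with placement-value variance, chi-square AUC
comparisons, and five-fold cross-validation of the screening pipeline.

The AUC is the Mann–Whitney U-statistic (ties credited 1/2): the
probability that the model scores a randomly chosen depressed window above
a randomly chosen normal one.  Its variance, and the covariance between two
AUCs computed on the same observations, use the structural-components
(placement-value) estimator, i.e. the DeLong construction: per positive,
the fraction of negatives it outranks, and vice versa.

Comparisons are chi-square with 1 df (a squared z), matching the form

    paired:   (A1 - A2)^2 / Var(A1 - A2),  Var from shared placements;
    unpaired: (A1 - A2)^2 / (Var A1 + Var A2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.metrics import roc_curve

from .cohort import CohortTables
from .indicators import (
    APPROACHES,
    DEFAULT_WINDOW_LEN,
    CutoffSet,
    assign_windows,
    indicators_from_windowed,
)
from .relogit import PanelDesign, fit_relogit, predict_prob

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    var_auc: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": float(self.auc), "var_auc": float(self.var_auc),
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "fpr": [float(v) for v in self.fpr],
            "tpr": [float(v) for v in self.tpr],
        }


@dataclass
class AucComparison:
    auc_1: float
    auc_2: float
    statistic: float
    p_value: float
    paired: bool

    def to_dict(self) -> dict:
        return {"auc_1": float(self.auc_1), "auc_2": float(self.auc_2),
                "statistic": float(self.statistic),
                "p_value": float(self.p_value), "paired": self.paired}


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values (V10 per positive, V01 per negative)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present to compute an AUC")
    r_all = rankdata(np.concatenate([pos, neg]))
    v10 = (r_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (r_all[m:] - rankdata(neg)) / m
    return v10, v01


def auc_mw(scores, labels) -> RocResult:
    """Tie-aware Mann–Whitney AUC with structural-components variance."""
    labels = np.asarray(labels).astype(int)
    v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                     var_auc=var, n_pos=m, n_neg=n)


def compare_paired(scores_a, scores_b, labels) -> AucComparison:
    """DeLong chi-square test of two AUCs computed on the same observations."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = ((np.var(d10, ddof=1) if m > 1 else 0.0) / m
           + (np.var(d01, ddof=1) if n > 1 else 0.0) / n)
    diff = auc_a - auc_b
    if var <= 1e-14:
        if abs(diff) < 1e-12:
            return AucComparison(auc_a, auc_b, 0.0, 1.0, paired=True)
        raise ValueError("zero estimated variance with unequal AUCs")
    stat = diff * diff / var
    return AucComparison(auc_a, auc_b, float(stat),
                         float(chi2.sf(stat, df=1)), paired=True)


def compare_unpaired(roc_1: RocResult, roc_2: RocResult) -> AucComparison:
    """Chi-square test of AUC equality between two independent samples."""
    var = roc_1.var_auc + roc_2.var_auc
    diff = roc_1.auc - roc_2.auc
    if var <= 1e-14:
        if abs(diff) < 1e-12:
            return AucComparison(roc_1.auc, roc_2.auc, 0.0, 1.0, paired=False)
        raise ValueError("zero combined variance with unequal AUCs")
    stat = diff * diff / var
    return AucComparison(roc_1.auc, roc_2.auc, float(stat),
                         float(chi2.sf(stat, df=1)), paired=False)


def make_folds(labels: np.ndarray, n_folds: int = 5,
               rng: np.random.Generator | None = None,
               max_attempts: int = 20) -> list[np.ndarray]:
    """Random near-equal partition of observation indices into folds.

    Fold sizes differ by at most one.  The partition is redrawn (up to
    ``max_attempts`` times) until every fold contains both outcome classes,
    so each training set and test set supports a fit and an AUC.
    """
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} observations for {n_folds} folds")
    rng = np.random.default_rng() if rng is None else rng
    for _ in range(max_attempts):
        folds = np.array_split(rng.permutation(n), n_folds)
        if all(len(np.unique(labels[f])) == 2 for f in folds):
            return folds
    raise RuntimeError(
        f"could not draw a {n_folds}-fold partition with both classes in "
        f"every fold after {max_attempts} attempts")


@dataclass
class CvResult:
    fold_aucs: list[float]
    pooled_auc: float
    fold_sizes: list[int]
    fold_cutoffs: list[CutoffSet | None]
    approach: str
    fold_test_keys: list[list[tuple]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "pooled_auc": float(self.pooled_auc),
            "fold_sizes": self.fold_sizes,
            "fold_cutoffs": [None if c is None else
                             {"sleep": c.sleep, "mood": c.mood, "anxiety": c.anxiety}
                             for c in self.fold_cutoffs],
        }


def five_fold_cv(
    cohort: CohortTables,
    approach: str,
    seed: int,
    window_len: int = DEFAULT_WINDOW_LEN,
    exclude_same_day: bool = False,
    n_folds: int = 5,
    quad_points: int = 15,
) -> CvResult:
    """Out-of-sample screening accuracy by k-fold cross-validation.

    Observations (patient-window rows with all three items reported) are
    partitioned at the row level into near-equal folds.  For the ratio and
    frequency approaches the dichotomization cutoffs are re-optimized on
    each training set — never on held-out rows — before the model is fit on
    the training rows and probabilities are predicted for the held-out
    fold.  Returns per-fold AUCs plus the AUC of pooled out-of-fold
    predictions.
    """
    from .cutoffs import optimize_all_windowed  # local import: cutoffs imports roc

    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    windowed = assign_windows(cohort.ratings, cohort.outcomes,
                              window_len, exclude_same_day)
    # any approach with no cutoffs needed enumerates the same complete windows
    full = indicators_from_windowed(
        windowed, cohort.outcomes, "average", None, window_len)
    keys = list(zip(full["patient_id"], full["window_end"]))
    labels = full["depressed"].to_numpy()
    rng = np.random.default_rng(seed)
    folds = make_folds(labels, n_folds, rng)

    key_index = pd.MultiIndex.from_tuples(keys, names=["patient_id", "window_end"])
    windowed_keys = pd.MultiIndex.from_arrays(
        [windowed["patient_id"], windowed["window_end"]])

    fold_aucs, fold_sizes, fold_cutoffs, test_keys_out = [], [], [], []
    pooled_scores = np.full(len(keys), np.nan)

    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(keys)), test_idx)
        train_keys = key_index[train_idx]
        test_keys = key_index[test_idx]
        w_train = windowed[windowed_keys.isin(train_keys)]
        w_test = windowed[windowed_keys.isin(test_keys)]

        cutoffs = None
        if approach in ("ratio", "frequency"):
            cutoffs = optimize_all_windowed(
                w_train, cohort.outcomes, approach,
                window_len=window_len, quad_points=quad_points).cutoffs
        train_tab = indicators_from_windowed(
            w_train, cohort.outcomes, approach, cutoffs, window_len)
        test_tab = indicators_from_windowed(
            w_test, cohort.outcomes, approach, cutoffs, window_len)

        fit = fit_relogit(PanelDesign.from_indicators(train_tab),
                          quad_points=quad_points)
        probs = predict_prob(fit, test_tab)
        fold_aucs.append(auc_mw(probs, test_tab["depressed"].to_numpy()).auc)
        fold_sizes.append(len(test_idx))
        fold_cutoffs.append(cutoffs)
        test_keys_out.append(list(test_keys))

        pos = {k: p for k, p in zip(
            zip(test_tab["patient_id"], test_tab["window_end"]), probs)}
        for idx in test_idx:
            pooled_scores[idx] = pos[keys[idx]]
        logger.info("fold %d/%d: n=%d, AUC=%.4f", f + 1, n_folds,
                    len(test_idx), fold_aucs[-1])

    pooled_auc = auc_mw(pooled_scores, labels).auc
    return CvResult(fold_aucs=fold_aucs, pooled_auc=pooled_auc,
                    fold_sizes=fold_sizes, fold_cutoffs=fold_cutoffs,
                    approach=approach, fold_test_keys=test_keys_out)
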