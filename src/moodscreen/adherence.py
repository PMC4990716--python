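"""Self-reporting adherence: four per-patient dimensions, k-means grouping,
and the effect of adherence on screening accuracy.

The four dimensions, all computed from the daily-ratings table:

* **activeness** — distinct days with at least one reported rating;
* **timeliness** — of those days, how many were reported the same day
  (any back-filled report counts as delayed);
* **duration** — complete 14-day intervals spanned between the patient's
  first and last reported day, ``floor(span / 14)``;
* **persistence** — distinct calendar 14-day bins (anchored at the study
  origin) containing at least one reported day.

Duration measures how long the patient stayed with the app; persistence
additionally penalizes long silent stretches inside that span.  Patients
are grouped by k-means (k = 2: higher/lower adherence) on the standardized
four-dimensional profile; a one-dimensional response-rate-only grouping
reproduces the simpler convention of earlier mobile-PRO studies.  Screening
accuracy is then compared between groups by running the whole pipeline
(cutoff search, panel fit, prediction, AUC) inside each group and applying
the unpaired chi-square AUC test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import CohortTables
from .indicators import DEFAULT_WINDOW_LEN, assign_windows, indicators_from_windowed
from .relogit import PanelDesign, fit_relogit, predict_prob
from .roc import AucComparison, RocResult, auc_mw, compare_unpaired

logger = logging.getLogger(__name__)

DEFAULT_PERIOD_DAYS = 14
ADHERENCE_FEATURES = ("activeness", "timeliness", "duration", "persistence")
GROUP_ORDER = {2: ("higher", "lower"), 3: ("higher", "middle", "lower")}


def adherence_metrics(
    ratings: pd.DataFrame,
    period_days: int = DEFAULT_PERIOD_DAYS,
    calendar_origin=None,
) -> pd.DataFrame:
    """Per-patient adherence profile (unclustered).

    ``calendar_origin`` anchors the persistence bins; defaults to the
    earliest target date in the table (the study start).
    """
    if ratings.empty:
        raise ValueError("cannot compute adherence for a patient with no ratings")
    origin = (pd.Timestamp(calendar_origin) if calendar_origin is not None
              else ratings["target_date"].min())

    per_day = (ratings.groupby(["patient_id", "target_date"])["report_date"]
                      .min().reset_index())
    per_day["on_time"] = per_day["report_date"] == per_day["target_date"]
    per_day["bin"] = (per_day["target_date"] - origin).dt.days // period_days

    g = per_day.groupby("patient_id")
    out = pd.DataFrame({
        "activeness": g.size(),
        "timeliness": g["on_time"].sum().astype(int),
        "duration": ((g["target_date"].max() - g["target_date"].min())
                     .dt.days // period_days),
        "persistence": g["bin"].nunique(),
    }).reset_index()
    return out


@dataclass
class ClusterModel:
    k: int
    features: list[str]
    means: np.ndarray
    sds: np.ndarray
    centroids: np.ndarray      # on the standardized scale
    assignment: pd.Series      # patient_id -> raw cluster id
    wcss: float
    seed: int
    n_restarts: int


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
    features=ADHERENCE_FEATURES,
) -> ClusterModel:
    """Lloyd's k-means on standardized adherence features.

    Best within-cluster sum of squares over ``n_restarts`` seeded random
    initializations; deterministic given ``seed``.  Zero-variance features
    are dropped with a warning (they cannot separate anyone).
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} patients")
    feats = list(features)
    X = profiles[feats].to_numpy(dtype=float)
    sds = X.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [f for f, ok in zip(feats, keep) if not ok]
        logger.warning("dropping zero-variance feature(s): %s", dropped)
        feats = [f for f, ok in zip(feats, keep) if ok]
        X, sds = X[:, keep], sds[keep]
        if X.shape[1] == 0:
            raise ValueError("all adherence features are constant; cannot cluster")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    km = KMeans(n_clusters=k, init="random", n_init=n_restarts,
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(Z)
    return ClusterModel(
        k=k, features=feats, means=means, sds=sds, centroids=km.cluster_centers_,
        assignment=pd.Series(labels, index=profiles["patient_id"].to_numpy()),
        wcss=float(km.inertia_), seed=seed, n_restarts=n_restarts,
    )


def label_groups(model: ClusterModel, profiles: pd.DataFrame) -> pd.Series:
    """Map raw cluster ids to adherence labels, ordered by mean activeness.

    Highest mean activeness → ``higher``; ties broken by mean persistence.
    Returns patient_id → label.
    """
    if model.k not in GROUP_ORDER:
        raise ValueError(f"labels defined for k in {sorted(GROUP_ORDER)}, got k={model.k}")
    prof = profiles.set_index("patient_id")
    stats = pd.DataFrame({
        "cluster": model.assignment,
        "activeness": prof.loc[model.assignment.index, "activeness"].to_numpy(),
        "persistence": prof.loc[model.assignment.index, "persistence"].to_numpy(),
    }).groupby("cluster").mean()
    if stats["activeness"].duplicated().any():
        logger.warning("clusters tied on mean activeness; breaking tie by persistence")
    order = stats.sort_values(["activeness", "persistence"],
                              ascending=False).index.to_list()
    name_of = dict(zip(order, GROUP_ORDER[model.k]))
    return model.assignment.map(name_of)


def response_rate_grouping(
    cohort: CohortTables,
    window_len: int = DEFAULT_WINDOW_LEN,
    seed: int = 0,
    n_restarts: int = 50,
) -> pd.Series:
    """The single-dimension grouping of earlier mobile-PRO studies.

    Per patient: the mean, over their PHQ-9 windows, of reported days / 14;
    then one-dimensional k-means with k = 2, the higher-rate cluster
    labelled ``higher``.
    """
    windowed = assign_windows(cohort.ratings, cohort.outcomes, window_len)
    days = (windowed.groupby(["patient_id", "window_end"])["target_date"]
                    .nunique().reset_index(name="days"))
    rate = (days.assign(rate=days["days"] / window_len)
                .groupby("patient_id")["rate"].mean().reset_index())
    model = kmeans_cluster(rate, k=2, n_restarts=n_restarts, seed=seed,
                           features=("rate",))
    centers = rate.set_index("patient_id").loc[model.assignment.index, "rate"] \
                  .groupby(model.assignment.to_numpy()).mean()
    higher = centers.idxmax()
    return model.assignment.map(lambda c: "higher" if c == higher else "lower")


@dataclass
class GroupAucResult:
    group_rocs: dict[str, RocResult]
    comparison: AucComparison        # higher vs lower
    approach: str
    cutoffs: dict[str, dict | None]


def group_auc_comparison(
    cohort: CohortTables,
    grouping: pd.Series,
    approach: str,
    window_len: int = DEFAULT_WINDOW_LEN,
    exclude_same_day: bool = False,
    quad_points: int = 15,
) -> GroupAucResult:
    """Run the full screening pipeline inside each adherence group and test
    AUC equality (unpaired chi-square) between ``higher`` and ``lower``."""
    from .cutoffs import optimize_all_windowed

    rocs: dict[str, RocResult] = {}
    cuts: dict[str, dict | None] = {}
    for label in sorted(grouping.unique()):
        pids = set(grouping.index[grouping == label])
        sub_r = cohort.ratings[cohort.ratings["patient_id"].isin(pids)]
        sub_o = cohort.outcomes[cohort.outcomes["patient_id"].isin(pids)]
        if sub_o["depressed"].nunique() < 2:
            raise ValueError(f"group {label!r} lacks one outcome class; "
                             "cannot compute its AUC")
        windowed = assign_windows(sub_r, sub_o, window_len, exclude_same_day)
        cutoffs = None
        if approach in ("ratio", "frequency"):
            search = optimize_all_windowed(windowed, sub_o, approach,
                                           window_len, quad_points)
            cutoffs = search.cutoffs
        table = indicators_from_windowed(windowed, sub_o, approach,
                                         cutoffs, window_len)
        fit = fit_relogit(PanelDesign.from_indicators(table), quad_points)
        probs = predict_prob(fit, table)
        rocs[label] = auc_mw(probs, table["depressed"].to_numpy())
        cuts[label] = None if cutoffs is None else {
            "sleep": cutoffs.sleep, "mood": cutoffs.mood, "anxiety": cutoffs.anxiety}
    comparison = compare_unpaired(rocs["higher"], rocs["lower"])
    return GroupAucResult(group_rocs=rocs, comparison=comparison,
                          approach=approach, cutoffs=cuts)


def robustness_filters(cohort: CohortTables, mode: str = "none",
                       period_days: int = DEFAULT_PERIOD_DAYS) -> CohortTables:
    """Subsample filters probing entry-timing bias in the adherence analysis.

    ``first_24_weeks`` keeps each patient's ratings and outcomes within 168
    days of their own first reported day; ``drop_late_starters`` removes
    patients whose first reported day falls in the final 84 days (12 weeks)
    of the observed study window; ``none`` is the identity.
    """
    if mode == "none":
        return cohort
    first = cohort.ratings.groupby("patient_id")["target_date"].min()
    if mode == "first_24_weeks":
        limit = cohort.ratings["patient_id"].map(first) + pd.Timedelta(days=167)
        ratings = cohort.ratings[cohort.ratings["target_date"] <= limit]
        olimit = cohort.outcomes["patient_id"].map(first) + pd.Timedelta(days=167)
        outcomes = cohort.outcomes[cohort.outcomes["test_date"] <= olimit]
    elif mode == "drop_late_starters":
        study_end = cohort.ratings["target_date"].max()
        threshold = study_end - pd.Timedelta(days=83)
        keep = first.index[first < threshold]
        ratings = cohort.ratings[cohort.ratings["patient_id"].isin(keep)]
        outcomes = cohort.outcomes[cohort.outcomes["patient_id"].isin(keep)]
    else:
        raise ValueError(f"unknown robustness mode {mode!r}")
    if ratings.empty or outcomes.empty:
        raise ValueError(f"robustness filter {mode!r} left an empty cohort")
    return CohortTables(ratings=ratings.reset_index(drop=True),
                        outcomes=outcomes.reset_index(drop=True))
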