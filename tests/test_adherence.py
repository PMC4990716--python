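"""Adherence dimensions, clustering, grouping and robustness filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_phq9, make_ratings
from moodscreen.adherence import (
    adherence_metrics,
    group_auc_comparison,
    kmeans_cluster,
    label_groups,
    response_rate_grouping,
    robustness_filters,
)
from moodscreen.cohort import CohortTables
from moodscreen.simulate import make_adherence_contrast_config, simulate_cohort

ORIGIN = "2013-04-01"


def _daily(pid, days, delay=0, origin=ORIGIN):
    start = pd.Timestamp(origin)
    rows = []
    for d in days:
        t = start + pd.Timedelta(days=int(d))
        rows.append((pid, t, t + pd.Timedelta(days=delay), "mood", 3))
    return rows


def _profile(rows):
    return adherence_metrics(make_ratings(rows), calendar_origin=ORIGIN) \
        .set_index("patient_id")


class TestMetrics:
    def test_four_weeks_of_on_time_daily_reports(self):
        p = _profile(_daily("p1", range(28))).loc["p1"]
        assert (p["activeness"], p["timeliness"],
                p["duration"], p["persistence"]) == (28, 28, 1, 2)

    def test_two_delayed_reports_two_weeks_apart(self):
        p = _profile(_daily("p1", [0, 15], delay=2)).loc["p1"]
        assert (p["activeness"], p["timeliness"],
                p["duration"], p["persistence"]) == (2, 0, 1, 2)

    def test_single_report(self):
        p = _profile(_daily("p1", [3])).loc["p1"]
        assert (p["activeness"], p["duration"], p["persistence"]) == (1, 0, 1)

    def test_no_ratings_rejected(self):
        with pytest.raises(ValueError, match="no ratings"):
            adherence_metrics(make_ratings([]).iloc[0:0])

    def test_earliest_report_decides_timeliness(self):
        # same day reported twice for different items, one on time
        start = pd.Timestamp(ORIGIN)
        rows = [("p1", start, start, "mood", 3),
                ("p1", start, start + pd.Timedelta(days=2), "sleep", 4)]
        p = _profile(rows).loc["p1"]
        assert p["timeliness"] == 1

    @given(days=st.sets(st.integers(0, 120), min_size=1, max_size=40))
    def test_persistence_bounded_by_duration(self, days):
        # calendar-anchored bins: a span of d complete periods can straddle
        # one extra bin boundary, so the bound is d + 2; anchoring bins at
        # the patient's own first report tightens it to d + 1
        days = sorted(days)
        p = _profile(_daily("p1", days)).loc["p1"]
        assert p["persistence"] <= p["duration"] + 2
        assert 0 <= p["timeliness"] <= p["activeness"]
        assert p["persistence"] >= 1
        own = pd.Timestamp(ORIGIN) + pd.Timedelta(days=days[0])
        rows = _daily("p1", days)
        q = adherence_metrics(make_ratings(rows), calendar_origin=own) \
            .set_index("patient_id").loc["p1"]
        assert q["persistence"] <= q["duration"] + 1

    @given(days=st.sets(st.integers(0, 80), min_size=2, max_size=20))
    def test_adding_a_day_never_decreases_activeness_or_persistence(self, days):
        days = sorted(days)
        smaller = _profile(_daily("p1", days[:-1])).loc["p1"]
        larger = _profile(_daily("p1", days)).loc["p1"]
        assert larger["activeness"] >= smaller["activeness"]
        assert larger["persistence"] >= smaller["persistence"]

    def test_on_time_conversion_adds_exactly_one_timeliness(self):
        delayed = _profile(_daily("p1", [0, 5, 9], delay=1)).loc["p1"]
        rows = _daily("p1", [0, 5], delay=1) + _daily("p1", [9], delay=0)
        mixed = _profile(rows).loc["p1"]
        assert mixed["timeliness"] == delayed["timeliness"] + 1


def _blob_profiles():
    rng = np.random.default_rng(0)
    hi = pd.DataFrame({
        "patient_id": [f"h{i}" for i in range(10)],
        "activeness": rng.integers(140, 180, 10),
        "timeliness": rng.integers(100, 140, 10),
        "duration": rng.integers(12, 17, 10),
        "persistence": rng.integers(12, 16, 10),
    })
    lo = pd.DataFrame({
        "patient_id": [f"l{i}" for i in range(20)],
        "activeness": rng.integers(10, 60, 20),
        "timeliness": rng.integers(5, 45, 20),
        "duration": rng.integers(1, 7, 20),
        "persistence": rng.integers(1, 7, 20),
    })
    return pd.concat([hi, lo], ignore_index=True)


class TestClustering:
    def test_separated_blobs_recovered_exactly(self):
        profiles = _blob_profiles()
        model = kmeans_cluster(profiles, k=2, seed=1)
        labels = label_groups(model, profiles)
        assert (labels[labels.index.str.startswith("h")] == "higher").all()
        assert (labels[labels.index.str.startswith("l")] == "lower").all()

    def test_k_equals_n_gives_zero_wcss(self):
        profiles = _blob_profiles().head(6)
        model = kmeans_cluster(profiles, k=6, seed=0, n_restarts=20)
        assert model.wcss == pytest.approx(0.0, abs=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(_blob_profiles().head(3), k=4, seed=0)

    def test_zero_variance_feature_dropped_with_warning(self, caplog):
        profiles = _blob_profiles()
        profiles["duration"] = 5
        with caplog.at_level("WARNING"):
            model = kmeans_cluster(profiles, k=2, seed=0)
        assert "duration" in caplog.text
        assert "duration" not in model.features

    def test_best_of_restarts_never_worse(self):
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(40)],
            "activeness": rng.integers(0, 200, 40),
            "timeliness": rng.integers(0, 150, 40),
            "duration": rng.integers(0, 20, 40),
            "persistence": rng.integers(0, 20, 40),
        })
        w1 = kmeans_cluster(profiles, k=3, n_restarts=1, seed=7).wcss
        w25 = kmeans_cluster(profiles, k=3, n_restarts=25, seed=7).wcss
        assert w25 <= w1 + 1e-9

    def test_small_instance_attains_exhaustive_optimum(self):
        rng = np.random.default_rng(9)
        profiles = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(8)],
            "activeness": rng.integers(0, 200, 8),
            "timeliness": rng.integers(0, 150, 8),
            "duration": rng.integers(0, 20, 8),
            "persistence": rng.integers(0, 20, 8),
        })
        model = kmeans_cluster(profiles, k=2, n_restarts=100, seed=0)
        Z = (profiles[model.features] - model.means) / model.sds
        Z = Z.to_numpy()
        best = np.inf
        for size in range(1, 8):
            for combo in itertools.combinations(range(8), size):
                a = np.zeros(8, bool)
                a[list(combo)] = True
                w = (((Z[a] - Z[a].mean(0)) ** 2).sum()
                     + ((Z[~a] - Z[~a].mean(0)) ** 2).sum())
                best = min(best, w)
        assert model.wcss == pytest.approx(best, rel=1e-9)

    def test_three_group_labels_follow_activeness_order(self):
        profiles = _blob_profiles()
        mid = profiles["patient_id"].str.startswith("h")
        profiles.loc[mid, "activeness"] //= 1  # keep as is
        extra = pd.DataFrame({
            "patient_id": [f"m{i}" for i in range(10)],
            "activeness": np.arange(80, 100, 2),
            "timeliness": np.arange(60, 80, 2),
            "duration": np.full(10, 9),
            "persistence": np.full(10, 9),
        })
        profiles = pd.concat([profiles, extra], ignore_index=True)
        model = kmeans_cluster(profiles, k=3, seed=2)
        labels = label_groups(model, profiles)
        means = profiles.set_index("patient_id").groupby(labels)["activeness"].mean()
        assert means["higher"] > means["middle"] > means["lower"]


class TestGrouping:
    def test_response_rate_separates_clean_rates(self):
        rows, outs = [], []
        rates = {"pa": 14, "pb": 13, "pc": 3, "pd": 2}
        for pid, k in rates.items():
            rows += _daily(pid, range(k))
            outs.append((pid, pd.Timestamp(ORIGIN) + pd.Timedelta(days=13), 9))
        cohort = CohortTables(ratings=make_ratings(rows),
                              outcomes=make_phq9(outs))
        g = response_rate_grouping(cohort)
        assert g["pa"] == g["pb"] == "higher"
        assert g["pc"] == g["pd"] == "lower"

    def test_burst_reporter_splits_the_two_conventions(self):
        # 14/14 days in a single fortnight then silence: a perfect response
        # rate but no persistence -> composite says lower, rate says higher
        g = simulate_cohort(make_adherence_contrast_config(n_patients=60),
                            seed=42)
        cohort = g.tables
        burst_rows = _daily("burst", range(14))
        ratings = pd.concat([cohort.ratings, make_ratings(burst_rows)],
                            ignore_index=True)
        outs = pd.concat([
            cohort.outcomes,
            make_phq9([("burst", pd.Timestamp(ORIGIN) + pd.Timedelta(days=13), 9)]),
        ], ignore_index=True)
        cohort2 = CohortTables(ratings=ratings, outcomes=outs)
        rate_groups = response_rate_grouping(cohort2)
        profiles = adherence_metrics(cohort2.ratings)
        composite = label_groups(kmeans_cluster(profiles, k=2, seed=0), profiles)
        assert rate_groups["burst"] == "higher"
        assert composite["burst"] == "lower"


class TestGroupComparison:
    def test_identical_groups_give_zero_statistic(self, small_cohort):
        cohort = small_cohort.tables
        pids = cohort.outcomes["patient_id"].unique()
        # duplicate the cohort under two disjoint id namespaces
        r2 = cohort.ratings.copy(); r2["patient_id"] = "c_" + r2["patient_id"]
        o2 = cohort.outcomes.copy(); o2["patient_id"] = "c_" + o2["patient_id"]
        both = CohortTables(
            ratings=pd.concat([cohort.ratings, r2], ignore_index=True),
            outcomes=pd.concat([cohort.outcomes, o2], ignore_index=True))
        grouping = pd.Series(
            ["higher"] * len(pids) + ["lower"] * len(pids),
            index=list(pids) + ["c_" + p for p in pids])
        res = group_auc_comparison(both, grouping, "average")
        assert res.comparison.statistic == pytest.approx(0.0, abs=1e-12)

    def test_no_spurious_effect_under_zero_gap(self):
        # identical adherence classes: rejections should track the 5% level
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            g = simulate_cohort(
                make_adherence_contrast_config(gap=0.0, n_patients=100),
                seed=7000 + seed)
            truth = g.patients.copy()
            rng = np.random.default_rng(seed)
            labels = pd.Series(
                rng.permutation(np.r_[["higher"] * 25, ["lower"] * 75]),
                index=truth["patient_id"].to_numpy())
            try:
                res = group_auc_comparison(g.tables, labels, "average")
            except ValueError:
                continue
            rejections += res.comparison.p_value < 0.05
        assert rejections / n_seeds <= 0.15

    def test_degenerate_group_named_in_error(self, small_cohort):
        cohort = small_cohort.tables
        pids = list(cohort.outcomes["patient_id"].unique())
        # put a single always-depressed patient alone in "higher"
        one = cohort.outcomes.groupby("patient_id")["depressed"].nunique()
        lone = one[one == 1].index[0]
        grouping = pd.Series(
            ["higher" if p == lone else "lower" for p in pids], index=pids)
        with pytest.raises(ValueError, match="higher"):
            group_auc_comparison(cohort, grouping, "average")


class TestRobustnessFilters:
    def _cohort(self):
        rows = _daily("early", range(0, 210, 7))       # 30 weeks of data
        rows += _daily("late", [300, 307])             # joins near the end
        outs = [("early", pd.Timestamp(ORIGIN) + pd.Timedelta(days=13), 9),
                ("late", pd.Timestamp(ORIGIN) + pd.Timedelta(days=313), 3)]
        return CohortTables(ratings=make_ratings(rows), outcomes=make_phq9(outs))

    def test_first_24_weeks_truncates_per_patient(self):
        cohort = self._cohort()
        out = robustness_filters(cohort, "first_24_weeks")
        early = out.ratings[out.ratings["patient_id"] == "early"]
        span = (early["target_date"].max() - early["target_date"].min()).days
        assert span <= 167
        # the late patient's short series is untouched
        assert (out.ratings["patient_id"] == "late").sum() == 2

    def test_late_starters_removed(self):
        out = robustness_filters(self._cohort(), "drop_late_starters")
        assert set(out.ratings["patient_id"]) == {"early"}
        assert set(out.outcomes["patient_id"]) == {"early"}

    def test_none_is_identity(self):
        cohort = self._cohort()
        out = robustness_filters(cohort, "none")
        pd.testing.assert_frame_equal(out.ratings, cohort.ratings)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown robustness mode"):
            robustness_filters(self._cohort(), "bogus")

    def test_emptying_filter_rejected(self):
        rows = _daily("p1", [330, 331])
        outs = [("p1", pd.Timestamp(ORIGIN) + pd.Timedelta(days=335), 9)]
        cohort = CohortTables(ratings=make_ratings(rows), outcomes=make_phq9(outs))
        with pytest.raises(ValueError, match="empty"):
            robustness_filters(cohort, "drop_late_starters")
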