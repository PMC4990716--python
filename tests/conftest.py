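import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from moodscreen.cohort import CohortTables, validate_phq9, validate_ratings
from moodscreen.relogit import ConvergenceWarning
from moodscreen.simulate import SimConfig, simulate_cohort

warnings.filterwarnings("ignore", category=ConvergenceWarning)


def make_ratings(rows):
    """Build a validated ratings frame from (pid, target, report, item, score)."""
    df = pd.DataFrame(rows, columns=[
        "patient_id", "target_date", "report_date", "item", "score"])
    return validate_ratings(df)


def make_phq9(rows, cutoff=5):
    """Build a validated PHQ-9 frame from (pid, test_date, score)."""
    df = pd.DataFrame(rows, columns=["patient_id", "test_date", "score"])
    return validate_phq9(df, cutoff)


def daily_rows(pid, start, scores_by_item, delay=0):
    """Rows for consecutive daily reports starting at ``start``."""
    start = pd.Timestamp(start)
    rows = []
    for item, scores in scores_by_item.items():
        for j, s in enumerate(scores):
            d = start + pd.Timedelta(days=j)
            rows.append((pid, d, d + pd.Timedelta(days=delay), item, s))
    return rows


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient, 24-week synthetic cohort shared across tests."""
    return simulate_cohort(SimConfig(n_patients=40, n_weeks=24, seed=101))


@pytest.fixture(scope="session")
def full_reporting_cohort():
    """Everyone reports every day, never delayed, no dropout."""
    from moodscreen.simulate import AdherenceClass
    cls = AdherenceClass(share=1.0, p_report=1.0, p_delay=0.0,
                         delay_max_days=1, dropout_hazard=0.0,
                         noise_multiplier=1.0)
    cfg = SimConfig(n_patients=30, n_weeks=20, adherence_classes=(cls,), seed=77)
    return simulate_cohort(cfg)


@pytest.fixture()
def cohort_csvs(tmp_path, small_cohort):
    from moodscreen.cohort import write_table
    rpath = tmp_path / "daily_ratings.csv"
    ppath = tmp_path / "phq9.csv"
    write_table(small_cohort.tables.ratings, rpath)
    write_table(small_cohort.tables.outcomes.drop(columns=["depressed"]), ppath)
    return rpath, ppath
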