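"""Synthetic cohorts with the longitudinal structure the screening model assumes.

The generator emulates a mobile mental-health tracker deployment: patients
enter a 48-week study at staggered dates, rate sleep dissatisfaction, mood
and anxiety daily (with gaps, delayed back-filled reports, and eventual
dropout) and take a PHQ-9 every 14 days while active.

Data-generating model, per patient *i*:

* random intercept ``u_i ~ N(0, tau^2)`` — stable severity differences;
* biweekly latent severity ``s_it = mu + u_i + x_it`` with a stationary
  AR(1) state ``x_it = rho * x_i,t-1 + N(0, sigma_state^2)``;
* PHQ-9 at the end of period *t*:
  ``clip(round(phq9_slope * s_it + N(0, phq9_noise)), 0, 27)``;
* each day *j* in period *t* and item *k*: latent
  ``s_it + N(0, sigma_day * noise_multiplier)`` (independent per item),
  mapped to the item scale as ``clip(round(offset_k + loading_k * latent))``.

Because both the daily ratings and the PHQ-9 load on the same latent state,
the association the random-intercept logistic screening model estimates is
present by construction, with strength controlled by the noise parameters.

Adherence heterogeneity comes from discrete classes: each class sets the
daily reporting probability, the chance and extent of late (back-filled)
reporting, a per-period geometric dropout hazard, and a day-level noise
multiplier, so low-adherence patients report less, later, for a shorter
time and with noisier scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_DEPRESSION_CUTOFF,
    ITEM_RANGES,
    ITEMS,
    CohortTables,
    validate_phq9,
    validate_ratings,
)


@dataclass(frozen=True)
class AdherenceClass:
    """Reporting-behaviour parameters for one latent adherence class."""

    share: float
    p_report: float
    p_delay: float
    delay_max_days: int
    dropout_hazard: float
    noise_multiplier: float


# Two classes approximating the observed cohort: roughly three quarters of
# patients report sparsely, late and drop out early; one quarter report
# almost daily with clean scores.
DEFAULT_CLASSES = (
    AdherenceClass(share=0.75, p_report=0.40, p_delay=0.40,
                   delay_max_days=3, dropout_hazard=0.20, noise_multiplier=2.0),
    AdherenceClass(share=0.25, p_report=0.95, p_delay=0.05,
                   delay_max_days=3, dropout_hazard=0.01, noise_multiplier=1.0),
)


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort.

    Scale defaults put the marginal rating means near the observed cohort
    (sleep ≈ 5, mood ≈ 3.2, anxiety ≈ 4.2) and the PHQ-9 mean near the
    screening cutoff, so roughly half the biweekly windows are depressed.
    """

    n_patients: int = 78
    n_weeks: int = 48
    phq9_period_days: int = 14
    mu: float = 4.5
    tau: float = 1.5
    rho: float = 0.6
    sigma_state: float = 1.0
    sigma_day: float = 2.5
    loading: dict = field(default_factory=lambda: {"sleep": 1.0, "mood": 0.55, "anxiety": 1.0})
    item_offset: dict = field(default_factory=lambda: {"sleep": 0.5, "mood": 0.71, "anxiety": -0.3})
    phq9_slope: float = 1.0
    phq9_noise: float = 1.75
    depression_cutoff: int = DEFAULT_DEPRESSION_CUTOFF
    adherence_classes: tuple = DEFAULT_CLASSES
    study_start: str = "2013-04-01"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_weeks * 7 < self.phq9_period_days:
            raise ValueError("study shorter than one PHQ-9 period")
        if not math.isclose(sum(c.share for c in self.adherence_classes), 1.0,
                            abs_tol=1e-9):
            raise ValueError("adherence class shares must sum to 1")
        for c in self.adherence_classes:
            for p in (c.p_report, c.p_delay):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {p} outside [0,1]")
            if not 0.0 <= c.dropout_hazard <= 1.0:
                raise ValueError("dropout_hazard outside [0,1]")
        if self.tau < 0 or self.sigma_state < 0 or self.sigma_day < 0:
            raise ValueError("tau and sigmas must be nonnegative")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1 (stationary AR(1))")

    @property
    def study_days(self) -> int:
        return self.n_weeks * 7


@dataclass
class GeneratedCohort:
    """Synthetic tables plus the ground truth behind them."""

    tables: CohortTables
    patients: pd.DataFrame  # patient_id, adherence_class, u, entry_day, n_periods
    windows: pd.DataFrame   # patient_id, test_date, latent, depressed_true

    @property
    def truth_grouping(self) -> pd.Series:
        """True adherence-class labels, highest class index = 'higher'."""
        top = self.patients["adherence_class"].max()
        labels = np.where(self.patients["adherence_class"] == top, "higher", "lower")
        return pd.Series(labels, index=self.patients["patient_id"].to_numpy())


def simulate_cohort(config: SimConfig, seed: int | None = None) -> GeneratedCohort:
    """Draw one cohort; deterministic given (config, seed).

    ``seed`` overrides ``config.seed`` when given; one of the two must be set
    for reproducible output (otherwise entropy from the OS is used).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    start = pd.Timestamp(config.study_start)
    period = config.phq9_period_days
    shares = np.array([c.share for c in config.adherence_classes])

    rating_rows: list[tuple] = []
    phq9_rows: list[tuple] = []
    patient_rows: list[tuple] = []
    window_rows: list[tuple] = []

    for i in range(config.n_patients):
        pid = f"p{i+1:04d}"
        cls_idx = int(rng.choice(len(shares), p=shares))
        cls = config.adherence_classes[cls_idx]
        entry = int(rng.integers(0, config.study_days - period + 1))
        available = (config.study_days - entry) // period
        if cls.dropout_hazard > 0:
            active = int(rng.geometric(cls.dropout_hazard))
        else:
            active = available
        n_periods = min(available, active)
        u = rng.normal(0.0, config.tau)
        patient_rows.append((pid, cls_idx, u, entry, n_periods))

        # stationary AR(1) state over biweekly periods
        if abs(config.rho) > 0:
            x = rng.normal(0.0, config.sigma_state / math.sqrt(1 - config.rho**2))
        else:
            x = rng.normal(0.0, config.sigma_state)
        day_sd = config.sigma_day * cls.noise_multiplier
        for t in range(n_periods):
            if t > 0:
                x = config.rho * x + rng.normal(0.0, config.sigma_state)
            s = config.mu + u + x
            test_day = entry + (t + 1) * period - 1
            test_date = start + pd.Timedelta(days=test_day)
            score = int(np.clip(round(config.phq9_slope * s
                                      + rng.normal(0.0, config.phq9_noise)), 0, 27))
            phq9_rows.append((pid, test_date, score))
            window_rows.append(
                (pid, test_date, s,
                 int(config.phq9_slope * s >= config.depression_cutoff))
            )
            for j in range(entry + t * period, entry + (t + 1) * period):
                if rng.random() > cls.p_report:
                    continue
                target = start + pd.Timedelta(days=j)
                if cls.p_delay > 0 and rng.random() < cls.p_delay:
                    delay = int(rng.integers(1, cls.delay_max_days + 1))
                else:
                    delay = 0
                report = target + pd.Timedelta(days=delay)
                for item in ITEMS:
                    lo, hi = ITEM_RANGES[item]
                    latent = s + rng.normal(0.0, day_sd)
                    raw = config.item_offset[item] + config.loading[item] * latent
                    rating_rows.append(
                        (pid, target, report, item, int(np.clip(round(raw), lo, hi)))
                    )

    ratings = pd.DataFrame(rating_rows, columns=[
        "patient_id", "target_date", "report_date", "item", "score"])
    outcomes = pd.DataFrame(phq9_rows, columns=["patient_id", "test_date", "score"])
    if outcomes.empty:
        raise ValueError("simulation produced no PHQ-9 outcomes; "
                         "check dropout and study length")
    tables = CohortTables(
        ratings=validate_ratings(ratings, source="simulated ratings"),
        outcomes=validate_phq9(outcomes, config.depression_cutoff,
                               source="simulated phq9"),
    )
    patients = pd.DataFrame(patient_rows, columns=[
        "patient_id", "adherence_class", "u", "entry_day", "n_periods"])
    windows = pd.DataFrame(window_rows, columns=[
        "patient_id", "test_date", "latent", "depressed_true"])
    return GeneratedCohort(tables=tables, patients=patients, windows=windows)


def make_adherence_contrast_config(
    gap: float = 1.0,
    n_patients: int = 150,
    low_share: float = 0.75,
    seed: int | None = None,
    **overrides,
) -> SimConfig:
    """A two-class config whose classes differ by a tunable adherence gap.

    ``gap = 1`` gives the default contrast (low class: half the reporting
    probability, frequent multi-day delays, ~6%/period dropout hazard and
    doubled day-level noise); ``gap = 0`` collapses both classes onto the
    high-adherence parameters, a null cohort with no adherence effect.
    Class shares default to 0.75/0.25, approximating the observed 58/20
    lower/higher split.
    """
    if not 0.0 <= gap:
        raise ValueError("gap must be nonnegative")
    high = AdherenceClass(share=1.0 - low_share, p_report=0.95, p_delay=0.05,
                          delay_max_days=3, dropout_hazard=0.01,
                          noise_multiplier=1.0)
    low = AdherenceClass(
        share=low_share,
        p_report=max(0.05, 0.95 - 0.55 * gap),
        p_delay=min(1.0, 0.05 + 0.35 * gap),
        delay_max_days=3,
        dropout_hazard=min(1.0, 0.01 + 0.19 * gap),
        noise_multiplier=1.0 + gap,
    )
    cfg = SimConfig(n_patients=n_patients, adherence_classes=(low, high), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
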