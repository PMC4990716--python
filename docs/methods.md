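# Methods

This note documents the statistical procedures `moodscreen` implements,
the design of the synthetic-cohort generator, and the numerical choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

Two tables drive everything. Daily ratings hold one row per (patient, day,
item) with an integer score: sleep dissatisfaction 0–10, mood 0–7, anxiety
0–10. Sleep is stored on the dissatisfaction scale so that all three items
increase with depression severity; if a raw export carries satisfaction,
the score is reversed (`10 − raw`) exactly once, at ingest, under an
explicit flag. Each rating carries both the day it refers to
(`target_date`) and the day it was submitted (`report_date`); apps allow
back-filling, so `report_date ≥ target_date` is enforced and the gap
defines "delayed" reporting. PHQ-9 outcomes hold one row per (patient,
test date) with the 0–27 total; the binary label is `score ≥ 5`. The low
cutoff favors sensitivity: in oncology settings the cost of missing
depression far exceeds the cost of a false alarm, so windows with even
mild symptoms are labelled depressed.

Validation is strict and names the offending row and field: out-of-range
scores, unknown items, future-dated reports and duplicate
(patient, day, item) rows are errors, not silent fixes. A patient may
report some items and not others on a given day; item streams are handled
independently downstream.

## Biweekly indicators

A rating with target date *d* belongs to the window of the PHQ-9 taken on
date *t* iff `t − 13 ≤ d ≤ t` — the 14 days ending on and including the
test day. If two tests of one patient are closer than 14 days, a rating
feeds only the earliest eligible window (logged), so no day is counted
twice. An `exclude_same_day` flag drops ratings with `d = t`, the
robustness subsample guarding against same-day contamination between the
ratings and the questionnaire.

Per item and window the three approaches are: **average** (mean raw
score), **frequency** (count of days with `score > cutoff`) and **ratio**
(that count divided by reported days). Dichotomization is strictly
greater-than; a day exactly at the cutoff counts as normal. Two exact
identities hold by construction and are property-tested: `frequency =
ratio × reported days`, and both are invariant to the order of days.

Windows where *any* item has zero reported days are excluded under all
three approaches. Ratio and average are undefined on empty sets, and
excluding uniformly keeps the three approaches comparable on identical
observation sets — which the paired comparison below requires. No
imputation of missing days is attempted.

## Cutoff selection

The ratio and frequency approaches need per-item thresholds. For each item
the search enumerates integer candidates from 1 to the scale maximum (10
candidates for the 0–10 scales, 7 for mood). The scale maximum makes every
day normal under strict `>` (a degenerate but valid candidate); 0 is
excluded because it would flag nearly every day. For each candidate the
item's indicator is rebuilt, a single-predictor random-intercept logistic
model is fitted, and the AUC of its predictions computed; the argmax wins,
with ties broken toward the smaller cutoff — the more sensitive screen,
consistent with prioritizing true positives. A candidate whose indicator
is constant (or whose outcome is one-class) scores 0.5 by convention.
Items are optimized independently; no joint three-dimensional search.

## Random-intercept logistic panel model

With `p_it = logistic(x_it'β + b_i)` and `b_i ~ N(0, σ_b²)`, the marginal
likelihood per patient integrates the Bernoulli product over `b_i`. The
integral is evaluated by (non-adaptive) Gauss–Hermite quadrature with the
change of variable `b = √2·σ_b·z`, 15 nodes by default — ample for short
panels; the likelihood moves by less than 1e−4 when doubling to 31 nodes
on well-conditioned fits, and matches brute-force adaptive quadrature to
1e−6 on tiny fixtures (both asserted in tests). A random rather than fixed
intercept keeps single-observation patients in the sample and avoids one
dummy per patient in a short panel.

Numerics: log-sum-exp across nodes for stability; analytic gradient; BFGS;
`σ_b` optimized on the log scale so nonnegativity is free, with boundary
solutions (σ̂ < 1e−3) reported as exactly 0. Starting values are the
pooled logistic fit with `σ_b = 0.5`. The coefficient covariance is the
inverse observed information (central-difference Hessian on the
(β, σ_b) scale; β block only when σ̂ is at the boundary). Setting
`fixed_sigma=0` profiles the likelihood at σ_b = 0 and reproduces ordinary
pooled logistic ML exactly — the nesting used as an oracle test.
(Quasi-)complete separation is flagged (`converged=False`), not raised:
the fitted ranking is still usable for ROC purposes.

Predicted probabilities are population-level, `logistic(x'β)` with the
random intercept at zero: screening a new patient supplies no posterior
for their `b_i`. Coefficients are interpreted through odds multipliers
`exp(δ·β)` for a δ change in an indicator.

## ROC, AUC and comparisons

The AUC is the Mann–Whitney U-statistic with ties credited ½, computed
from midranks; its variance uses the structural-components (placement
value) estimator: `Var = S₁₀/m + S₀₁/n` where `S₁₀` is the sample variance
of each positive's placement among negatives and vice versa. Two AUCs on
the same observations are compared by the DeLong construction — the
variance of the AUC difference from differenced placement values — and two
AUCs from independent groups by summing their variances; both tests use
the chi-square(1) form (a squared z, two-sided). Degenerate cases are
explicit: identical classifiers give statistic 0, p 1; zero estimated
variance with unequal AUCs is an error rather than an infinite statistic.

Five-fold cross-validation partitions observation rows (patient-windows)
into near-equal folds — 497 rows give sizes {99, 100} — redrawing the
partition (bounded attempts) until every fold contains both outcome
classes. Rows, not patients, are the unit because the fold-size convention
above matches row counts; a patient-level split avoiding within-patient
leakage across folds can be composed from the same primitives if desired,
and the documented caveat is that row-level splits share patients between
training and test folds. Within each fold the cutoffs are re-optimized on
the four training folds only (an instrumented test asserts the search
never sees held-out rows), the model is refitted, and held-out
probabilities are pooled for the out-of-fold AUC.

## Adherence

Four per-patient dimensions, all from the ratings table:

* **activeness** — distinct days with at least one reported rating;
* **timeliness** — those days whose earliest report was the same day; any
  back-fill counts as delayed;
* **duration** — `floor(span/14)`, complete 14-day intervals between first
  and last reported day;
* **persistence** — distinct calendar 14-day bins (anchored at the study
  origin, by default the earliest target date in the table) containing at
  least one reported day.

Duration and persistence deliberately differ: a patient active in week 1
and week 40 only has a long duration but persistence 2. With
calendar-anchored bins a span of *d* complete periods can straddle one
extra bin boundary, so `persistence ≤ duration + 2`; anchoring bins at the
patient's own first report (available via `calendar_origin`) tightens this
to `duration + 1`. Both bounds are property-tested.

Patients are grouped by k-means (Lloyd, 50 seeded random restarts, best
within-cluster sum of squares) on the four features standardized to zero
mean and unit variance — their raw scales differ by an order of magnitude,
so unstandardized clustering would be dominated by activeness.
Zero-variance features are dropped with a warning. Cluster labels are
assigned by mean activeness (ties by persistence): highest → "higher".
k = 2 by default; k = 3 (higher/middle/lower) supports the robustness
variant. The single-dimension alternative used by earlier mobile-PRO
studies — each patient's mean windowed response rate, clustered 1-D with
k = 2 — is provided for comparison; a "burst" reporter with a perfect rate
in a single fortnight and silence afterwards is classified higher by the
rate convention but lower by the composite one.

Group accuracy comparison runs the *entire* pipeline (cutoff search, fit,
prediction, AUC) inside each group's observations and applies the unpaired
chi-square test. Two robustness filters probe entry-timing bias:
`first_24_weeks` truncates each patient to 168 days from their own first
report; `drop_late_starters` removes patients whose first report falls in
the final 84 days of the observed study window.

## Synthetic cohort generator

The generator emulates the data-collection design the analysis assumes: a
48-week study, staggered uniform entry, daily three-item ratings, a PHQ-9
every 14 days while the patient is active. Per patient, a random intercept
`u_i ~ N(0, τ²)` and a stationary AR(1) state give biweekly latent
severity `s_it = μ + u_i + x_it`; the PHQ-9 is
`clip(round(slope·s_it + noise), 0, 27)` and each day's item rating is
`clip(round(offset_k + loading_k·(s_it + day noise)), scale)`, with the
day-level noise drawn independently per item so cross-item daily
correlations are realistic rather than forced to 1. Both the ratings and
the questionnaire load on the same latent state, so the association the
screening model estimates is present by construction and its strength is
config, not constant. Reporting behaviour comes from discrete adherence
classes: per-day reporting probability, probability and extent (1–3 days)
of delayed back-filling, a per-biweekly-period geometric dropout hazard
(dropout is a persistence construct, hence period- not day-granular), and
a day-noise multiplier. The PHQ-9 lapses after dropout.

Defaults were chosen once to reproduce the operating point reported for
the motivating cohort, and are not tuned thereafter: 78 patients, 48
weeks; `μ = 4.5, τ = 1.5, ρ = 0.6, σ_state = 1.0, σ_day = 2.5`, PHQ-9
slope 1 and noise SD 1.75; item offsets/loadings put marginal rating means
near 5.0/3.2/4.2 and roughly half of windows depressed. Two adherence
classes with shares 0.75/0.25 mirror the observed lower/higher split: the
low class reports 40% of days, delays 40% of reports, faces a 20%/period
dropout hazard (mean duration ≈ 4–5 periods versus ≈ 12 for the high
class's 1% hazard — matching the order-of-magnitude duration contrast seen
in practice) and has doubled day-level noise. Under these conditions the
simulated ratio-approach AUC sits near 0.80 overall, with
higher-adherence groups near 0.85 and lower near 0.77–0.79 — the regime
the pipeline is meant to operate in. `make_adherence_contrast_config(gap)`
scales the class contrast continuously; `gap = 0` is an exact null (both
classes identical) used for calibration tests.

What the generator does *not* emulate: PHQ-9 item-level structure,
seasonal or treatment-phase trends, informative missingness (reporting
probability is independent of the latent state given the class), and
floor/ceiling pile-ups beyond what clipping induces. Passing tests
therefore show that the pipeline recovers structure of this kind when it
is present — not that real cohorts contain it.

## Problem sizes in the test suite

Simulation-backed tests run at sizes chosen to make their assertions
stable: parameter recovery at 200 patients × 10 windows over 50
replicates; type-I calibration of the unpaired comparison over 200 null
replicates at 250 observations per group; the adherence-direction suite on
150-patient contrast cohorts over 25 seeds; planted-cutoff recovery over
10 seeds; the cross-validation optimism check on the 78-patient default
cohort over 3 partitions. The paired-comparison oracle is a 2000-replicate
stratified bootstrap at n = 300.

## Known limitations

* The composite error of the screening model is read as random intercept
  plus logistic residual; no serial correlation beyond the intercept is
  modelled, though the generator's AR(1) state induces some — the model is
  deliberately the simpler working specification.
* In-sample group AUC comparisons inherit optimism from within-group
  cutoff search and fitting; with few patients in a group the comparison
  is noisy (visible in the README's single-draw example).
* Wald confidence intervals for σ_b are poor near the boundary σ_b ≈ 0;
  coverage claims are tested away from it.
* Cross-validation partitions rows, so patients span folds; see above.
* The response-rate grouping uses 1-D k-means; a fixed-threshold variant
  of the same construct would group differently near the boundary.
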