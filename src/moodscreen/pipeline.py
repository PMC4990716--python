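"""End-to-end orchestration: data → indicators → cutoffs → fit → ROC →
cross-validation → adherence comparison, with full provenance.

Every run is a pure function of (input data or simulation config, run
configuration, seed); all JSON outputs carry the config hash and seed so a
run can be re-executed byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import adherence as adh
from . import cutoffs as cut
from .cohort import CohortTables, write_table
from .indicators import APPROACHES, DEFAULT_WINDOW_LEN, build_indicator_table
from .relogit import PanelDesign, fit_relogit, predict_prob
from .roc import auc_mw, compare_paired, five_fold_cv
from .simulate import AdherenceClass, SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries a machine-readable record."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.record = {"stage": stage, "error": type(cause).__name__,
                       "message": str(cause)}


@dataclass
class RunConfig:
    """One source of data (CSV paths or a simulation config) plus settings."""

    ratings_path: str | None = None
    phq9_path: str | None = None
    sim: SimConfig | None = None
    approaches: tuple = APPROACHES
    window_len: int = DEFAULT_WINDOW_LEN
    depression_cutoff: int = 5
    exclude_same_day: bool = False
    raw_sleep_is_satisfaction: bool = False
    run_cv: bool = True
    cv_folds: int = 5
    run_adherence: bool = True
    adherence_k: int = 2
    kmeans_restarts: int = 50
    quad_points: int = 15
    seed: int = 0
    outdir: str = "moodscreen_out"

    def __post_init__(self) -> None:
        from_files = self.ratings_path is not None and self.phq9_path is not None
        if from_files == (self.sim is not None):
            raise ValueError("exactly one data source: either both CSV paths "
                             "or a simulation config")
        bad = [a for a in self.approaches if a not in APPROACHES]
        if bad:
            raise ValueError(f"unknown approach(es) {bad}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "adherence_classes" in sim:
                sim["adherence_classes"] = tuple(
                    AdherenceClass(**c) for c in sim["adherence_classes"])
            raw["sim"] = SimConfig(**sim)
        if "approaches" in raw:
            raw["approaches"] = tuple(raw["approaches"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["approaches"] = list(self.approaches)
        if self.sim is not None:
            d["sim"]["adherence_classes"] = [
                dataclasses.asdict(c) for c in self.sim.adherence_classes]
        return d

    def config_hash(self) -> str:
        # hash the scientific configuration; where outputs land is irrelevant
        d = self.to_jsonable()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dump_json(obj: dict, path: Path, provenance: dict) -> None:
    payload = dict(obj)
    payload["_provenance"] = provenance
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_full(config: RunConfig) -> dict:
    """Execute every stage for every requested approach; returns the summary.

    Writes per-approach indicators.csv / cutoffs.json / fit.json / roc.json /
    cv.json, adherence.csv, comparison.json, and summary.{json,txt} into
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed}
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                     "approaches": {}, "comparisons": {},
                     "subsample": ("exclude_same_day" if config.exclude_same_day
                                   else "full")}
    t0 = time.time()

    def stage(name, fn, *args, **kwargs):
        t = time.time()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # halt with the stage name
            err = StageError(name, exc)
            _dump_json({"error": err.record}, outdir / "error.json", provenance)
            raise err from exc
        logger.info("stage %-22s %.2fs", name, time.time() - t)
        return result

    # --- data -----------------------------------------------------------
    if config.sim is not None:
        generated = stage("simulate", simulate_cohort, config.sim,
                          seed=config.seed)
        cohort = generated.tables
        write_table(cohort.ratings, outdir / "daily_ratings.csv")
        write_table(cohort.outcomes, outdir / "phq9.csv")
        truth = generated.windows.copy()
        truth["test_date"] = truth["test_date"].dt.strftime("%Y-%m-%d")
        truth.to_csv(outdir / "truth.csv", index=False, float_format="%.12g")
    else:
        cohort = stage("load", CohortTables.from_files,
                       config.ratings_path, config.phq9_path,
                       config.raw_sleep_is_satisfaction,
                       config.depression_cutoff)
    summary["n_patients"] = int(cohort.n_patients)
    summary["n_outcomes"] = int(len(cohort.outcomes))

    # --- per-approach screening ----------------------------------------
    probs_by_approach: dict[str, pd.Series] = {}
    for approach in config.approaches:
        cutoffs = None
        if approach in ("ratio", "frequency"):
            search = stage(f"cutoffs[{approach}]", cut.optimize_all, cohort,
                           approach, config.window_len, config.exclude_same_day,
                           config.quad_points)
            cutoffs = search.cutoffs
            _dump_json(search.to_dict(), outdir / f"cutoffs_{approach}.json",
                       provenance)
        table = stage(f"indicators[{approach}]", build_indicator_table, cohort,
                      approach, cutoffs, config.window_len,
                      config.exclude_same_day)
        write_table(table.drop(columns=[]), outdir / f"indicators_{approach}.csv")
        fit = stage(f"fit[{approach}]", fit_relogit,
                    PanelDesign.from_indicators(table), config.quad_points)
        _dump_json(fit.to_dict(), outdir / f"fit_{approach}.json", provenance)
        probs = predict_prob(fit, table)
        roc = stage(f"roc[{approach}]", auc_mw, probs,
                    table["depressed"].to_numpy())
        _dump_json(roc.to_dict(), outdir / f"roc_{approach}.json", provenance)
        probs_by_approach[approach] = pd.Series(
            probs, index=pd.MultiIndex.from_frame(
                table[["patient_id", "window_end"]]))
        entry = {"auc": roc.auc, "var_auc": roc.var_auc,
                 "n_obs": fit.n_obs, "sigma_b": fit.sigma_b,
                 "beta": dict(zip(fit.names, map(float, fit.beta)))}
        if cutoffs is not None:
            entry["cutoffs"] = {"sleep": cutoffs.sleep, "mood": cutoffs.mood,
                                "anxiety": cutoffs.anxiety}
        if config.run_cv:
            cv = stage(f"cv[{approach}]", five_fold_cv, cohort, approach,
                       config.seed, config.window_len, config.exclude_same_day,
                       config.cv_folds, config.quad_points)
            _dump_json(cv.to_dict(), outdir / f"cv_{approach}.json", provenance)
            entry["cv_pooled_auc"] = cv.pooled_auc
            entry["cv_fold_aucs"] = [float(a) for a in cv.fold_aucs]
        summary["approaches"][approach] = entry

    # --- paired approach comparisons (shared observations) --------------
    if "ratio" in probs_by_approach:
        for other in ("average", "frequency"):
            if other not in probs_by_approach:
                continue
            a = probs_by_approach["ratio"]
            b = probs_by_approach[other].reindex(a.index)
            labels = (cohort.outcomes.set_index(
                ["patient_id", "test_date"])["depressed"].reindex(a.index))
            cmp = stage(f"compare[ratio vs {other}]", compare_paired,
                        a.to_numpy(), b.to_numpy(), labels.to_numpy())
            summary["comparisons"][f"ratio_vs_{other}"] = cmp.to_dict()

    # --- adherence ------------------------------------------------------
    if config.run_adherence:
        profiles = stage("adherence_metrics", adh.adherence_metrics,
                         cohort.ratings, config.window_len)
        model = stage("kmeans", adh.kmeans_cluster, profiles,
                      config.adherence_k, config.kmeans_restarts, config.seed)
        labels = adh.label_groups(model, profiles)
        profiles["cluster"] = profiles["patient_id"].map(labels)
        write_table(profiles, outdir / "adherence.csv")
        group_cmp = {}
        for approach in config.approaches:
            try:
                res = stage(f"group_auc[{approach}]", adh.group_auc_comparison,
                            cohort, labels, approach, config.window_len,
                            config.exclude_same_day, config.quad_points)
            except StageError as err:
                group_cmp[approach] = {"error": err.record}
                continue
            group_cmp[approach] = {
                "aucs": {g: r.auc for g, r in res.group_rocs.items()},
                "comparison": res.comparison.to_dict(),
                "cutoffs": res.cutoffs,
            }
        _dump_json(group_cmp, outdir / "comparison.json", provenance)
        summary["adherence"] = {
            "k": config.adherence_k,
            "group_sizes": labels.value_counts().to_dict(),
            "group_auc": group_cmp,
        }

    logger.info("run complete in %.2fs", time.time() - t0)
    _dump_json(summary, outdir / "summary.json", provenance)
    (outdir / "summary.txt").write_text(_render_summary(summary))
    return summary


def _render_summary(summary: dict) -> str:
    lines = [
        "moodscreen run summary",
        f"  sample: {summary['subsample']}  seed: {summary['seed']}  "
        f"config: {summary['config_hash']}",
        f"  patients: {summary['n_patients']}  PHQ-9 outcomes: {summary['n_outcomes']}",
        "",
        "  screening accuracy by approach",
    ]
    for name, e in summary["approaches"].items():
        lines.append(f"    {name:<10} AUC {e['auc']:.4f}"
                     + (f"  (CV pooled {e['cv_pooled_auc']:.4f})"
                        if "cv_pooled_auc" in e else ""))
        if "cutoffs" in e:
            c = e["cutoffs"]
            lines.append(f"    {'':<10} cutoffs sleep>{c['sleep']} "
                         f"mood>{c['mood']} anxiety>{c['anxiety']}")
    if summary["comparisons"]:
        lines.append("")
        lines.append("  paired AUC comparisons")
        for name, c in summary["comparisons"].items():
            lines.append(f"    {name:<20} chi2 {c['statistic']:.3f}  "
                         f"p {c['p_value']:.4f}")
    if "adherence" in summary:
        lines.append("")
        lines.append("  adherence groups (k-means on activeness/timeliness/"
                     "duration/persistence)")
        sizes = summary["adherence"]["group_sizes"]
        lines.append("    sizes: " + ", ".join(f"{g}={n}" for g, n in sizes.items()))
        for approach, e in summary["adherence"]["group_auc"].items():
            if "error" in e:
                lines.append(f"    {approach:<10} [failed: "
                             f"{e['error']['message']}]")
                continue
            aucs = "  ".join(f"{g} {a:.4f}" for g, a in e["aucs"].items())
            lines.append(f"    {approach:<10} {aucs}  "
                         f"p {e['comparison']['p_value']:.4f}")
    lines.append("")
    return "\n".join(lines)
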