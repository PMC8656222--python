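"""End-to-end orchestration: simulate -> triage -> adjudicate -> metrics -> cost.

:func:`run_pipeline` executes the whole semi-automated screening workflow
on a synthetic cohort and writes a reproducible run directory:

* ``cohort.csv`` (+ ``cohort.csv.params.yaml``) — the simulated images;
* ``selection.csv`` — images flagged for human review, with reasons;
* ``reference.csv`` — adjudicated reference grades;
* ``workflow.csv`` — per-image automated decision, final label, source;
* ``metrics.json`` — accuracy layer on the reviewed subset and, since the
  simulation knows the truth, on the full cohort;
* ``per_year.csv`` — a per-visit-year summary (counts, AUC, sensitivity,
  specificity, accuracy) plus a pooled row;
* ``cost.csv`` / ``cost.json`` — the grading-cost comparison;
* ``manifest.json`` — config, seed and versions.

One global seed drives everything: the cohort, triage QA sampling and
grader draws read from independently derived substreams, so re-running the
same config is bit-identical, and changing one component's noise does not
perturb the others.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .adjudication import AdjudicationConfig, ReferenceGrade, adjudicate
from .classifier import ClassifierModel
from .cohort import Cohort, CohortParams, simulate_cohort
from .cost import CostParams, cost_evaluate, rounded_savings
from .grades import referable
from .metrics import accuracy_sens_spec, confusion, roc_auc, weighted_kappa
from .rng import derive_seed, substream
from .triage import (NEGATIVE, POSITIVE, UNGRADABLE, TriageConfig,
                     WorkflowResult, assemble_workflow_result,
                     dla_decide_cohort, select_for_review)

__all__ = ["RunConfig", "PipelineRun", "run_pipeline",
           "adjudicate_selection", "reviewed_metrics", "yearly_summary"]


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one workflow run."""

    cohort: CohortParams = field(default_factory=CohortParams)
    classifier: ClassifierModel = field(default_factory=ClassifierModel)
    triage: TriageConfig = field(default_factory=TriageConfig)
    adjudication: AdjudicationConfig = field(
        default_factory=AdjudicationConfig)
    cost: CostParams = field(default_factory=CostParams)
    seed: int = 0
    auc_bootstrap: int = 500

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["cohort"]["years"] = list(self.cohort.years)
        for g in d["adjudication"]["panel"]:
            g["wrong_referable_grade"] = str(g["wrong_referable_grade"])
            g["wrong_non_referable_grade"] = str(
                g["wrong_non_referable_grade"])
        s = d["adjudication"]["senior"]
        s["wrong_referable_grade"] = str(s["wrong_referable_grade"])
        s["wrong_non_referable_grade"] = str(s["wrong_non_referable_grade"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        from .grades import GradeLabel
        from .graders import GraderProfile

        def grader(g: Mapping) -> GraderProfile:
            g = dict(g)
            for key in ("wrong_referable_grade", "wrong_non_referable_grade"):
                g[key] = GradeLabel(g[key])
            return GraderProfile(**g)

        adj = d["adjudication"]
        return cls(
            cohort=CohortParams(**d["cohort"]),
            classifier=ClassifierModel(**d["classifier"]),
            triage=TriageConfig(**d["triage"]),
            adjudication=AdjudicationConfig(
                panel=tuple(grader(g) for g in adj["panel"]),
                senior=grader(adj["senior"]),
                consensus_rule=adj["consensus_rule"]),
            cost=CostParams(**d["cost"]),
            seed=int(d["seed"]),
            auc_bootstrap=int(d.get("auc_bootstrap", 500)))


@dataclass
class PipelineRun:
    """In-memory results of one pipeline execution."""

    cohort: Cohort
    decisions: pd.Series
    selection: list
    reference: dict[str, ReferenceGrade]
    result: WorkflowResult
    metrics: dict
    per_year: pd.DataFrame
    cost: dict


def adjudicate_selection(cohort: Cohort, selection,
                         cfg: AdjudicationConfig,
                         rng: np.random.Generator,
                         ) -> dict[str, ReferenceGrade]:
    """Adjudicate every selected gradable image, in stable image order."""
    selected = {s.image_id for s in selection}
    out: dict[str, ReferenceGrade] = {}
    for rec in cohort.records():
        if rec.image_id in selected and rec.gradable:
            out[rec.image_id] = adjudicate(rec, cfg, rng)
    return out


def reviewed_metrics(cohort: Cohort, decisions: pd.Series,
                     reference: Mapping[str, ReferenceGrade], *,
                     seed: int = 0, n_boot: int = 500) -> dict:
    """Accuracy layer on the human-reviewed gradable subset.

    This is the partial-verification evaluation a triage deployment can
    actually perform: automated decisions versus the adjudicated reference,
    restricted to reviewed images.
    """
    ids = [iid for iid in decisions.index if iid in reference]
    dec = decisions.loc[ids]
    ref = pd.Series({iid: reference[iid].is_referable for iid in ids})
    cm = confusion(dec, ref)
    acc = accuracy_sens_spec(cm)
    kap = weighted_kappa(cm.as_table())
    scores = cohort.frame.set_index("image_id").loc[ids, "score"]
    auc_res = None
    if 0 < ref.sum() < len(ref):
        auc_res = roc_auc(scores.to_numpy(), ref.to_numpy(),
                          n_boot=n_boot, seed=seed)
    return {
        "n_reviewed_gradable": len(ids),
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "accuracy": acc.accuracy,
        "sensitivity": acc.sensitivity,
        "specificity": acc.specificity,
        "kappa": kap.kappa,
        "kappa_ci": [kap.ci_low, kap.ci_high],
        "auc": auc_res.auc if auc_res else None,
        "auc_ci": ([auc_res.ci_low, auc_res.ci_high]
                   if auc_res and auc_res.ci_low is not None else None),
        "cutoff": auc_res.cutoff if auc_res else None,
    }


def full_cohort_metrics(cohort: Cohort, decisions: pd.Series, *,
                        seed: int = 0, n_boot: int = 0) -> dict:
    """Accuracy layer against simulated truth on all gradable images —
    the verification-bias-free surface only a simulation can provide."""
    f = cohort.frame[cohort.frame["gradable"].astype(bool)]
    ids = f["image_id"]
    dec = decisions.loc[ids]
    truth = f["true_grade"].map(referable)
    truth.index = ids
    cm = confusion(dec, truth)
    acc = accuracy_sens_spec(cm)
    out = {
        "n_gradable": len(ids),
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "accuracy": acc.accuracy,
        "sensitivity": acc.sensitivity,
        "specificity": acc.specificity,
    }
    if 0 < truth.sum() < len(truth):
        auc_res = roc_auc(f["score"].to_numpy(), truth.to_numpy(),
                          n_boot=n_boot, seed=seed)
        out["auc"] = auc_res.auc
        out["cutoff"] = auc_res.cutoff
    return out


def yearly_summary(cohort: Cohort, decisions: pd.Series, selection,
                   reference: Mapping[str, ReferenceGrade]) -> pd.DataFrame:
    """Per-visit-year counts and reviewed-subset accuracy, plus a pooled
    row. The pooled AUC is computed two ways (pooled scores across years,
    and the mean of the yearly AUCs) since multi-year summaries can
    reasonably aggregate either way."""
    f = cohort.frame.set_index("image_id")
    sel_ids = {s.image_id for s in selection}
    rows = []
    yearly_aucs = []
    years = sorted(f["visit_year"].unique())

    def block(sub: pd.DataFrame, label) -> dict:
        dec = decisions.loc[sub.index]
        rev = [iid for iid in sub.index
               if iid in sel_ids and iid in reference]
        ref = pd.Series({iid: reference[iid].is_referable for iid in rev},
                        dtype=bool)
        row = {
            "year": label,
            "included": len(sub),
            "positive": int((dec == POSITIVE).sum()),
            "negative": int((dec == NEGATIVE).sum()),
            "ungradable": int((dec == UNGRADABLE).sum()),
            "reviewed": int(sum(iid in sel_ids for iid in sub.index)),
            "human_positive": int(ref.sum()),
            "auc": None, "sensitivity": None, "specificity": None,
            "accuracy": None,
        }
        if rev:
            cm = confusion(dec.loc[rev], ref)
            acc = accuracy_sens_spec(cm)
            row.update(accuracy=acc.accuracy, sensitivity=acc.sensitivity,
                       specificity=acc.specificity)
            if 0 < ref.sum() < len(ref):
                scores = sub.loc[rev, "score"].to_numpy()
                row["auc"] = roc_auc(scores, ref.to_numpy(), n_boot=0).auc
        return row

    for year in years:
        row = block(f[f["visit_year"] == year], int(year))
        rows.append(row)
        if row["auc"] is not None:
            yearly_aucs.append(row["auc"])
    pooled = block(f, "pooled")
    pooled["auc_mean_of_years"] = (float(np.mean(yearly_aucs))
                                   if yearly_aucs else None)
    rows.append(pooled)
    table = pd.DataFrame(rows)
    if "auc_mean_of_years" not in table.columns:
        table["auc_mean_of_years"] = None
    return table


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None,
                 ) -> PipelineRun:
    """Execute the full workflow; optionally write the run directory."""
    cohort_params = replace(cfg.cohort,
                            rng_seed=derive_seed(cfg.seed, "cohort"))
    triage_cfg = replace(cfg.triage,
                         rng_seed=derive_seed(cfg.seed, "triage"))

    cohort = simulate_cohort(cohort_params, cfg.classifier)
    decisions = dla_decide_cohort(cohort, cfg.classifier)
    selection = select_for_review(cohort, decisions, triage_cfg)
    rng_adj = substream(cfg.seed, "adjudication")
    reference = adjudicate_selection(cohort, selection, cfg.adjudication,
                                     rng_adj)
    result = assemble_workflow_result(cohort, decisions, selection,
                                      reference)

    metrics = {
        "reviewed": reviewed_metrics(
            cohort, decisions, reference,
            seed=derive_seed(cfg.seed, "metrics"), n_boot=cfg.auc_bootstrap),
        "full_cohort_vs_truth": full_cohort_metrics(cohort, decisions),
        "counts": result.counts(),
    }
    per_year = yearly_summary(cohort, decisions, selection, reference)
    n_reviewed_gradable = metrics["reviewed"]["n_reviewed_gradable"]
    cost_report = cost_evaluate(cohort.n_images, n_reviewed_gradable,
                                cfg.cost)
    save_t, save_c = rounded_savings(cost_report)
    cost = cost_report.as_dict()
    cost["saving_time_fraction_rounded_inputs"] = save_t
    cost["saving_cost_fraction_rounded_inputs"] = save_c

    run = PipelineRun(cohort=cohort, decisions=decisions,
                      selection=selection, reference=reference,
                      result=result, metrics=metrics, per_year=per_year,
                      cost=cost)
    if out_dir is not None:
        _write_run(run, cfg, cohort_params, Path(out_dir))
    return run


def _write_run(run: PipelineRun, cfg: RunConfig,
               cohort_params: CohortParams, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    run.cohort.to_csv(out / "cohort.csv", params=cohort_params)
    pd.DataFrame([{"image_id": s.image_id, "reason": s.reason}
                  for s in run.selection]).to_csv(
        out / "selection.csv", index=False)
    pd.DataFrame([{"image_id": r.image_id, "grade": str(r.grade),
                   "path": r.path, "n_graders_used": r.n_graders_used}
                  for r in run.reference.values()]).to_csv(
        out / "reference.csv", index=False)
    run.result.to_csv(out / "workflow.csv")
    (out / "metrics.json").write_text(
        json.dumps(run.metrics, indent=2, sort_keys=True,
                   default=_json_default))
    run.per_year.round(3).to_csv(out / "per_year.csv", index=False)
    (out / "cost.json").write_text(
        json.dumps(run.cost, indent=2, sort_keys=True,
                   default=_json_default))
    _cost_csv(run.cost).to_csv(out / "cost.csv", index=False)
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "versions": {"python": sys.version.split()[0],
                     "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True,
                   default=_json_default))


def _cost_csv(cost: dict) -> pd.DataFrame:
    rows = []
    for strat in ("fully_human", "fully_auto", "semi_auto"):
        s = cost[strat]
        rows.append({
            "strategy": strat,
            "total_time_hours": round(s["total_time_hours"], 3),
            "mean_time_min_per_image": round(
                s["mean_time_min_per_image"], 3),
            "total_cost": round(s["total_cost"], 2),
            "mean_cost_per_image": round(s["mean_cost_per_image"], 3),
        })
    return pd.DataFrame(rows)
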