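"""Two-step semi-automated triage workflow.

Step 1: the automated classifier grades every image as POSITIVE (score at
or above the operating threshold), NEGATIVE, or UNGRADABLE (image quality
too poor to score).

Step 2: a subset is flagged for human regrading —

* every automated POSITIVE (reason ``DLA_POSITIVE``);
* all other available images of any patient with at least one positive,
  including their negative and (configurably) ungradable images
  (reason ``PATIENT_LINKED``);
* a seeded simple random sample, without replacement, of the remaining
  automated negatives, as a quality-assurance audit of the classifier's
  negative calls (reason ``QA_SAMPLE``; default fraction 5%).

Reasons are assigned with priority DLA_POSITIVE > PATIENT_LINKED >
QA_SAMPLE, so each image appears at most once. Final workflow labels take
the adjudicated human reference for reviewed gradable images and the
automated decision everywhere else.

QA sampling uses a fixed seeded permutation of the eligible pool and takes
its first *k* elements, so enlarging ``qa_fraction`` only ever adds images
to the selection.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adjudication import ReferenceGrade
from .classifier import ClassifierModel
from .cohort import Cohort, ImageRecord
from .grades import GradeLabel, referable
from .rng import substream

__all__ = ["DLADecision", "TriageConfig", "SelectionRecord", "WorkflowResult",
           "dla_decide", "dla_decide_cohort", "select_for_review",
           "assemble_workflow_result"]

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
UNGRADABLE = "UNGRADABLE"

REASON_POSITIVE = "DLA_POSITIVE"
REASON_LINKED = "PATIENT_LINKED"
REASON_QA = "QA_SAMPLE"


class DLADecision(str, enum.Enum):
    """Automated three-way decision for one image."""

    POSITIVE = POSITIVE
    NEGATIVE = NEGATIVE
    UNGRADABLE = UNGRADABLE

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class TriageConfig:
    """Knobs of the review-selection step."""

    qa_fraction: float = 0.05
    qa_count_override: int | None = None
    include_ungradable_linked: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.qa_fraction <= 1.0:
            raise ValueError("qa_fraction must lie in [0, 1]")
        if self.qa_count_override is not None and self.qa_count_override < 0:
            raise ValueError("qa_count_override must be non-negative")


@dataclass(frozen=True)
class SelectionRecord:
    """One image flagged for human regrading, with the winning reason."""

    image_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in (REASON_POSITIVE, REASON_LINKED, REASON_QA):
            raise ValueError(f"unknown selection reason: {self.reason!r}")


def dla_decide(image: ImageRecord, model: ClassifierModel) -> DLADecision:
    """Automated decision for a single image (UNGRADABLE if not gradable,
    else POSITIVE iff score >= threshold; the boundary counts positive)."""
    if not image.gradable:
        return DLADecision.UNGRADABLE
    return (DLADecision.POSITIVE if image.score >= model.threshold
            else DLADecision.NEGATIVE)


def dla_decide_cohort(cohort: Cohort, model: ClassifierModel) -> pd.Series:
    """Vectorised decisions for a whole cohort (Series indexed by image_id)."""
    f = cohort.frame
    dec = np.where(~f["gradable"].to_numpy(dtype=bool), UNGRADABLE,
                   np.where(f["score"].to_numpy() >= model.threshold,
                            POSITIVE, NEGATIVE))
    return pd.Series(dec, index=f["image_id"].to_numpy(), name="dla_decision")


def _check_decisions(cohort: Cohort, decisions: pd.Series) -> pd.Series:
    ids = cohort.frame["image_id"]
    if set(decisions.index) != set(ids):
        raise ValueError("decisions must cover exactly the cohort's images")
    return decisions.reindex(ids)


def select_for_review(cohort: Cohort, decisions: pd.Series,
                      cfg: TriageConfig) -> list[SelectionRecord]:
    """Flag images for human regrading per the triage rules.

    Returns records ordered positives, patient-linked, QA sample (each
    block in cohort order). Deterministic given ``cfg.rng_seed``.

    Raises
    ------
    ValueError
        If decisions do not cover the cohort, or ``qa_count_override``
        exceeds the eligible negative pool.
    """
    decisions = _check_decisions(cohort, decisions)
    f = cohort.frame
    dec = decisions.to_numpy()

    is_pos = dec == POSITIVE
    flagged_patients = set(f.loc[is_pos, "patient_id"])
    linked = f["patient_id"].isin(flagged_patients).to_numpy() & ~is_pos
    if not cfg.include_ungradable_linked:
        linked &= dec != UNGRADABLE

    qa_pool = (~is_pos) & (~linked) & (dec == NEGATIVE)
    pool_ids = sorted(f.loc[qa_pool, "image_id"])
    if cfg.qa_count_override is not None:
        k = cfg.qa_count_override
        if k > len(pool_ids):
            raise ValueError(
                f"qa_count_override={k} exceeds the eligible negative "
                f"pool of {len(pool_ids)} images")
    else:
        k = int(round(cfg.qa_fraction * len(pool_ids)))
    rng = substream(cfg.rng_seed, "qa_sampling")
    qa_ids = set(np.array(pool_ids, dtype=object)[
        rng.permutation(len(pool_ids))[:k]]) if pool_ids else set()

    out: list[SelectionRecord] = []
    for iid in f.loc[is_pos, "image_id"]:
        out.append(SelectionRecord(iid, REASON_POSITIVE))
    for iid in f.loc[linked, "image_id"]:
        out.append(SelectionRecord(iid, REASON_LINKED))
    for iid in f["image_id"]:
        if iid in qa_ids:
            out.append(SelectionRecord(iid, REASON_QA))
    return out


class WorkflowResult:
    """Per-image outcome of the full semi-automated workflow.

    Wraps a frame with columns: image_id, dla_decision, selected, reason,
    reference_grade, final_label, label_source.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)

    @property
    def final_labels(self) -> pd.Series:
        s = self.frame.set_index("image_id")["final_label"]
        return s

    def counts(self) -> dict[str, int]:
        """Reconciliation counts: decisions partition, review reasons."""
        f = self.frame
        c = {
            "total": len(f),
            "dla_positive": int((f["dla_decision"] == POSITIVE).sum()),
            "dla_negative": int((f["dla_decision"] == NEGATIVE).sum()),
            "dla_ungradable": int((f["dla_decision"] == UNGRADABLE).sum()),
            "reviewed": int(f["selected"].sum()),
        }
        for reason, key in ((REASON_POSITIVE, "reason_positive"),
                            (REASON_LINKED, "reason_linked"),
                            (REASON_QA, "reason_qa")):
            c[key] = int((f["reason"] == reason).sum())
        c["final_positive"] = int((f["final_label"] == POSITIVE).sum())
        c["final_negative"] = int((f["final_label"] == NEGATIVE).sum())
        c["final_ungradable"] = int((f["final_label"] == UNGRADABLE).sum())
        return c

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def assemble_workflow_result(
        cohort: Cohort, decisions: pd.Series,
        selection: Sequence[SelectionRecord],
        reference_grades: Mapping[str, ReferenceGrade | GradeLabel],
) -> WorkflowResult:
    """Combine automated decisions and human reference grades.

    Selected gradable images take their final label from the human
    reference (POSITIVE iff the reference grade is referable, source
    HUMAN); every other image keeps its automated decision (source DLA).

    Raises
    ------
    ValueError
        If a selected gradable image has no reference grade.
    """
    decisions = _check_decisions(cohort, decisions)
    f = cohort.frame
    sel_reason = {s.image_id: s.reason for s in selection}

    rows = []
    gradable = dict(zip(f["image_id"], f["gradable"].astype(bool)))
    for iid, dec in zip(f["image_id"], decisions.to_numpy()):
        selected = iid in sel_reason
        ref_grade = None
        if selected and gradable[iid]:
            ref = reference_grades.get(iid)
            if ref is None:
                raise ValueError(f"missing reference grade for selected "
                                 f"image {iid}")
            ref_grade = ref.grade if isinstance(ref, ReferenceGrade) else ref
            final = POSITIVE if referable(ref_grade) else NEGATIVE
            source = "HUMAN"
        else:
            final = dec
            source = "DLA"
        rows.append((iid, dec, selected, sel_reason.get(iid),
                     str(ref_grade) if ref_grade is not None else None,
                     final, source))
    frame = pd.DataFrame(rows, columns=[
        "image_id", "dla_decision", "selected", "reason",
        "reference_grade", "final_label", "label_source"])
    return WorkflowResult(frame)
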