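"""Reference-standard adjudication.

Every image selected for human review is graded independently by a panel of
trained graders. If the panel is unanimous on the binary referable /
non-referable endpoint, that consensus is the reference standard; otherwise
the image goes to a senior ophthalmologist whose grade is conclusive.
Consensus is defined on referable status, not on the exact R-category,
because the screening endpoint (refer / do not refer) is binary.

The default senior grader is error-free: the workflow treats the senior's
diagnosis as the reference by fiat. A fallible senior can be configured for
sensitivity analyses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .cohort import ImageRecord
from .grades import GradeLabel, referable
from .graders import GraderProfile, grade_by_human

__all__ = ["AdjudicationConfig", "ReferenceGrade", "adjudicate"]


def _default_panel() -> tuple[GraderProfile, ...]:
    return tuple(GraderProfile(grader_id=f"grader{i}") for i in range(1, 4))


@dataclass(frozen=True)
class AdjudicationConfig:
    """Panel composition and consensus rule."""

    panel: tuple[GraderProfile, ...] = field(default_factory=_default_panel)
    senior: GraderProfile = GraderProfile(grader_id="senior", is_senior=True)
    consensus_rule: str = "unanimous_referable_status"

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("panel must be non-empty")
        if not self.senior.is_senior:
            raise ValueError("senior grader must have is_senior=True")
        if any(g.is_senior for g in self.panel):
            raise ValueError("panel graders must not be senior")
        if self.consensus_rule != "unanimous_referable_status":
            raise ValueError(f"unknown consensus rule: {self.consensus_rule!r}")


@dataclass(frozen=True)
class ReferenceGrade:
    """Adjudicated reference diagnosis for one image."""

    image_id: str
    grade: GradeLabel
    path: str  # "CONSENSUS" | "SENIOR"
    n_graders_used: int

    @property
    def is_referable(self) -> bool:
        return referable(self.grade)


def adjudicate(image: ImageRecord, cfg: AdjudicationConfig,
               rng: np.random.Generator) -> ReferenceGrade:
    """Adjudicate one gradable image.

    Draws one grade per panel member; unanimity on referable status yields
    a CONSENSUS reference (modal panel category, ties broken toward the
    less severe grade for determinism). Disagreement escalates to the
    senior grader, whose draw is conclusive.
    """
    if not image.gradable:
        raise ValueError(f"image {image.image_id} is not gradable")
    panel_grades = [grade_by_human(image, g, rng) for g in cfg.panel]
    statuses = {referable(g) for g in panel_grades}
    if len(statuses) == 1:
        counts = Counter(panel_grades)
        top = max(counts.values())
        modal = sorted((g for g, c in counts.items() if c == top),
                       key=lambda g: list(GradeLabel).index(g))[0]
        return ReferenceGrade(image_id=image.image_id, grade=modal,
                              path="CONSENSUS",
                              n_graders_used=len(cfg.panel))
    senior_grade = grade_by_human(image, cfg.senior, rng)
    return ReferenceGrade(image_id=image.image_id, grade=senior_grade,
                          path="SENIOR", n_graders_used=len(cfg.panel) + 1)
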