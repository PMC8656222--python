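"""Imperfect human graders.

Each grader is summarised by two operating characteristics on the binary
referable / non-referable endpoint: ``sens_h``, the probability a truly
referable image is graded referable, and ``spec_h``, the probability a
truly non-referable image is graded non-referable. When the grader lands on
the correct side it reports the true category exactly; when it errs it
reports a configured default category on the wrong side (R2 for a false
referable call, R1 for a missed referable case). Graders are conditionally
independent given the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ImageRecord
from .grades import GradeLabel, referable

__all__ = ["GraderProfile", "grade_by_human"]


@dataclass(frozen=True)
class GraderProfile:
    """One grader's binary operating characteristics."""

    grader_id: str
    sens_h: float = 1.0
    spec_h: float = 1.0
    is_senior: bool = False
    #: category reported when a non-referable image is wrongly called referable
    wrong_referable_grade: GradeLabel = GradeLabel.R2
    #: category reported when a referable image is wrongly called non-referable
    wrong_non_referable_grade: GradeLabel = GradeLabel.R1

    def __post_init__(self) -> None:
        if not 0.0 <= self.sens_h <= 1.0 or not 0.0 <= self.spec_h <= 1.0:
            raise ValueError("sens_h and spec_h must lie in [0, 1]")
        if referable(self.wrong_referable_grade) is not True:
            raise ValueError("wrong_referable_grade must be a referable grade")
        if referable(self.wrong_non_referable_grade):
            raise ValueError("wrong_non_referable_grade must be non-referable")


def grade_by_human(image: ImageRecord, grader: GraderProfile,
                   rng: np.random.Generator) -> GradeLabel:
    """Draw one grade for *image* from *grader*.

    With probability ``sens_h`` (truth referable) or ``spec_h`` (truth
    non-referable) the returned label sits on the truth's side of the
    referable divide and copies the true category; otherwise the grader's
    configured wrong-side default is returned.

    Raises
    ------
    ValueError
        If the image is not gradable (humans cannot grade it either).
    """
    if not image.gradable:
        raise ValueError(f"image {image.image_id} is not gradable")
    truth = GradeLabel(image.true_grade)
    if referable(truth):
        correct = rng.random() < grader.sens_h
        return truth if correct else grader.wrong_non_referable_grade
    correct = rng.random() < grader.spec_h
    return truth if correct else grader.wrong_referable_grade
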