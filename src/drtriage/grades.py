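"""NHS diabetic-retinopathy grade taxonomy.

The UK National Health Service screening taxonomy assigns each fundus
photograph one of five retinopathy grades: R0 (no DR), R1 (background DR),
R2 (pre-proliferative DR), R3a (active proliferative DR) and R3s (stable,
treated proliferative DR). "Referable DR" — vision-threatening disease that
warrants ophthalmology referral — is pre-proliferative disease or worse,
i.e. R2, R3a or R3s.
"""

from __future__ import annotations

from enum import Enum


class GradeLabel(str, Enum):
    """A single NHS retinopathy grade."""

    R0 = "R0"
    R1 = "R1"
    R2 = "R2"
    R3A = "R3a"
    R3S = "R3s"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Grades that constitute referable (vision-threatening) DR.
REFERABLE_GRADES = frozenset({GradeLabel.R2, GradeLabel.R3A, GradeLabel.R3S})

#: Grades on the non-referable side (no DR / background DR).
NON_REFERABLE_GRADES = frozenset({GradeLabel.R0, GradeLabel.R1})


def referable(grade: GradeLabel | str) -> bool:
    """True iff *grade* is referable DR (R2, R3a or R3s)."""
    return GradeLabel(grade) in REFERABLE_GRADES
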