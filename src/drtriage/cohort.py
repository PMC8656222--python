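"""Seeded synthetic screening cohorts.

Emulates the image structure of a longitudinal fundus-photography screening
programme: each patient contributes, at every attended annual visit, two
photographic fields per eye — F1 (optic-disc-centred) and F2
(macula-centred) — i.e. four images per patient-year. Every image carries a
true NHS grade (R0-R3s), a gradability flag (a few percent of real-world
fundus photographs are too poor in quality or positioning to grade), and,
when gradable, a continuous classifier score drawn from a
:class:`~drtriage.classifier.ClassifierModel` conditional on the eye's true
referable status.

Disease truth is assigned at the eye-year level: both fields of an eye in a
given year share one true grade, because retinopathy status is a property
of the eye, not of the photograph. Disease onset is drawn per patient
(uniform over the simulated years) and, by default, persists monotonically
once present.

The generator draws from named substreams ("truth", "quality", "scores")
derived from a single seed, so the cohort is byte-identical across runs and
each stochastic layer can be varied independently.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classifier import ClassifierModel
from .grades import GradeLabel, referable
from .rng import substream

__all__ = ["ImageRecord", "Cohort", "CohortParams", "simulate_cohort",
           "expected_image_prevalence"]

EYES = ("left", "right")
FIELDS = ("F1", "F2")

#: Grade mix among referable eye-years (mostly pre-proliferative disease in
#: a screening population) and among non-referable eye-years.
REFERABLE_GRADE_WEIGHTS = {GradeLabel.R2: 0.80, GradeLabel.R3A: 0.15,
                           GradeLabel.R3S: 0.05}
NON_REFERABLE_GRADE_WEIGHTS = {GradeLabel.R0: 0.85, GradeLabel.R1: 0.15}

COHORT_COLUMNS = ["image_id", "patient_id", "visit_year", "eye", "field",
                  "true_grade", "gradable", "score"]


@dataclass(frozen=True)
class ImageRecord:
    """One fundus photograph and everything the workflow knows about it."""

    image_id: str
    patient_id: str
    visit_year: int
    eye: str
    field: str
    true_grade: GradeLabel
    gradable: bool
    score: float | None = None

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.field not in FIELDS:
            raise ValueError(f"field must be one of {FIELDS}")
        has_score = self.score is not None and not (
            isinstance(self.score, float) and np.isnan(self.score))
        if has_score != self.gradable:
            raise ValueError("score must be present iff the image is gradable")
        if has_score and not 0.0 <= float(self.score) <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def is_referable(self) -> bool:
        return referable(self.true_grade)


@dataclass(frozen=True)
class CohortParams:
    """Generator knobs for one synthetic cohort.

    Parameters
    ----------
    n_patients
        Number of patients enrolled.
    years
        Strictly increasing visit years, e.g. ``[2009]`` for a baseline-only
        cohort or ``range(2011, 2018)`` for annual follow-up.
    p_referable_patient
        Probability a patient ever develops referable DR during the
        simulated years.
    p_ungradable
        Per-image probability of an ungradable photograph, independent of
        disease status.
    p_both_eyes
        Given a patient develops referable DR, probability both eyes are
        affected (otherwise one eye, chosen at random).
    progression_monotone
        If true (default), referable status persists in all years at or
        after onset; if false, it is present in the onset year only.
    attendance
        Optional mapping year -> attendance probability; missing years
        default to 1.0 (every patient attends).
    rng_seed
        Global seed; all substreams derive from it.
    """

    n_patients: int = 4900
    years: Sequence[int] = (2009,)
    p_referable_patient: float = 0.015
    p_ungradable: float = 0.0223
    p_both_eyes: float = 0.4
    progression_monotone: bool = True
    attendance: Mapping[int, float] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        years = list(self.years)
        if not years or any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be non-empty and strictly increasing")
        for name in ("p_referable_patient", "p_ungradable", "p_both_eyes"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.attendance is not None:
            for y, p in self.attendance.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"attendance[{y}] must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        if self.attendance is not None:
            d["attendance"] = {int(k): float(v)
                               for k, v in self.attendance.items()}
        return d


class Cohort:
    """Patient-linked collection of :class:`ImageRecord` rows.

    Backed by a pandas DataFrame (one row per image); ``patients`` is the
    grouping of image ids by patient id and is always exactly consistent
    with the rows.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(COHORT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"cohort frame missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        self.validate()

    # ---- invariants ----------------------------------------------------

    def validate(self) -> None:
        f = self.frame
        if f["image_id"].duplicated().any():
            raise ValueError("duplicate image_id in cohort")
        key = f[["patient_id", "visit_year", "eye", "field"]]
        if key.duplicated().any():
            raise ValueError("duplicate (patient, year, eye, field) in cohort")
        has_score = f["score"].notna()
        if (has_score != f["gradable"].astype(bool)).any():
            raise ValueError("score present iff gradable violated")
        sc = f.loc[has_score, "score"]
        if ((sc < 0) | (sc > 1)).any():
            raise ValueError("scores must lie in [0, 1]")
        f["true_grade"].map(GradeLabel)  # raises on unknown grade

    # ---- accessors -----------------------------------------------------

    @property
    def patients(self) -> dict[str, list[str]]:
        """Mapping patient_id -> list of that patient's image ids."""
        return self.frame.groupby("patient_id")["image_id"].agg(list).to_dict()

    @property
    def n_images(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[ImageRecord]:
        for row in self.frame.itertuples(index=False):
            yield ImageRecord(
                image_id=row.image_id, patient_id=row.patient_id,
                visit_year=int(row.visit_year), eye=row.eye, field=row.field,
                true_grade=GradeLabel(row.true_grade),
                gradable=bool(row.gradable),
                score=float(row.score) if not pd.isna(row.score) else None)

    def referable_truth(self) -> pd.Series:
        """Boolean Series (index image_id): true referable status."""
        ref = self.frame["true_grade"].map(referable)
        ref.index = self.frame["image_id"]
        return ref

    # ---- serialization -------------------------------------------------

    def to_csv(self, path: str | Path,
               params: CohortParams | None = None) -> None:
        """Write the flat per-image CSV; if *params* is given, write a YAML
        sidecar ``<path>.params.yaml`` with the generating parameters."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        if params is not None:
            sidecar = path.with_name(path.name + ".params.yaml")
            sidecar.write_text(yaml.safe_dump(params.to_dict(),
                                              sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        frame = pd.read_csv(path, dtype={"patient_id": str, "image_id": str})
        frame["gradable"] = frame["gradable"].astype(bool)
        return cls(frame)


def expected_image_prevalence(params: CohortParams) -> float:
    """Closed-form expected fraction of images whose truth is referable.

    Product of: P(patient ever referable), expected fraction of eyes
    affected, and expected fraction of a patient's years at/after a
    uniformly drawn onset (monotone progression) or exactly the onset year.
    Attendance and gradability are independent of disease status, so they
    do not move the image-level fraction.
    """
    y = len(list(params.years))
    eye_frac = params.p_both_eyes + (1.0 - params.p_both_eyes) * 0.5
    year_frac = (y + 1) / (2.0 * y) if params.progression_monotone else 1.0 / y
    return params.p_referable_patient * eye_frac * year_frac


def simulate_cohort(params: CohortParams,
                    classifier: ClassifierModel | None = None) -> Cohort:
    """Generate a cohort under *params*, scoring images with *classifier*.

    Each attended patient-year contributes exactly four images
    (2 eyes x 2 fields). Truth is drawn per eye-year and shared by the two
    fields; scores are drawn per image from the classifier's conditional
    distribution; ungradable images carry no score. Deterministic given
    ``params.rng_seed``.
    """
    if classifier is None:
        classifier = ClassifierModel()
    years = np.asarray(list(params.years))
    n_years = years.size
    n_pat = params.n_patients

    rng_truth = substream(params.rng_seed, "truth")
    rng_quality = substream(params.rng_seed, "quality")
    rng_scores = substream(params.rng_seed, "scores")

    # --- patient-level disease truth ---
    ever = rng_truth.random(n_pat) < params.p_referable_patient
    onset_idx = rng_truth.integers(0, n_years, size=n_pat)
    both_eyes = rng_truth.random(n_pat) < params.p_both_eyes
    which_eye = rng_truth.integers(0, 2, size=n_pat)  # if single eye
    # eye_affected[p, e]: eye e of patient p is an affected eye
    eye_affected = np.zeros((n_pat, 2), dtype=bool)
    eye_affected[np.arange(n_pat), which_eye] = True
    eye_affected[both_eyes, :] = True
    eye_affected &= ever[:, None]

    # --- attendance (all patients attend unless thinned) ---
    attendance = params.attendance or {}
    attend = np.ones((n_pat, n_years), dtype=bool)
    for j, year in enumerate(years):
        p = float(attendance.get(int(year), 1.0))
        if p < 1.0:
            attend[:, j] = rng_truth.random(n_pat) < p

    # --- expand to eye-year grid, then to images ---
    pat_idx, year_idx, eye_idx = np.meshgrid(
        np.arange(n_pat), np.arange(n_years), np.arange(2), indexing="ij")
    pat_idx, year_idx, eye_idx = (a.ravel() for a in
                                  (pat_idx, year_idx, eye_idx))
    keep = attend[pat_idx, year_idx]
    pat_idx, year_idx, eye_idx = pat_idx[keep], year_idx[keep], eye_idx[keep]

    if params.progression_monotone:
        active = year_idx >= onset_idx[pat_idx]
    else:
        active = year_idx == onset_idx[pat_idx]
    eye_year_ref = eye_affected[pat_idx, eye_idx] & active

    ref_grades = list(REFERABLE_GRADE_WEIGHTS)
    ref_w = np.fromiter(REFERABLE_GRADE_WEIGHTS.values(), float)
    non_grades = list(NON_REFERABLE_GRADE_WEIGHTS)
    non_w = np.fromiter(NON_REFERABLE_GRADE_WEIGHTS.values(), float)
    n_ey = pat_idx.size
    grade_choice = np.empty(n_ey, dtype=object)
    n_ref = int(eye_year_ref.sum())
    grade_choice[eye_year_ref] = rng_truth.choice(
        [g.value for g in ref_grades], size=n_ref, p=ref_w / ref_w.sum())
    grade_choice[~eye_year_ref] = rng_truth.choice(
        [g.value for g in non_grades], size=n_ey - n_ref,
        p=non_w / non_w.sum())

    # two fields per eye-year
    rep = np.repeat(np.arange(n_ey), 2)
    fields = np.tile(np.array(FIELDS), n_ey)
    n_img = rep.size
    is_ref_img = eye_year_ref[rep]

    gradable = rng_quality.random(n_img) >= params.p_ungradable
    scores = classifier.sample(is_ref_img, rng_scores)
    scores = np.where(gradable, scores, np.nan)

    pid = np.char.add("P", np.char.zfill(
        pat_idx[rep].astype(str), len(str(n_pat))))
    eye_codes = np.array(["L", "R"])
    frame = pd.DataFrame({
        "patient_id": pid,
        "visit_year": years[year_idx[rep]],
        "eye": np.array(EYES)[eye_idx[rep]],
        "field": fields,
        "true_grade": grade_choice[rep],
        "gradable": gradable,
        "score": scores,
    })
    frame.insert(0, "image_id",
                 frame["patient_id"] + "-"
                 + frame["visit_year"].astype(str) + "-"
                 + pd.Series(eye_codes[eye_idx[rep]]) + "-"
                 + frame["field"])
    return Cohort(frame)
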