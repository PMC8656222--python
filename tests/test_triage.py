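"""Triage engine: decisions, review selection, workflow assembly."""

import pandas as pd
import pytest

from drtriage import (ClassifierModel, Cohort, CohortParams, GradeLabel,
                      ImageRecord, TriageConfig, assemble_workflow_result,
                      dla_decide, dla_decide_cohort, select_for_review,
                      simulate_cohort)
from drtriage.grades import referable
from drtriage.triage import (NEGATIVE, POSITIVE, REASON_LINKED, REASON_QA,
                             REASON_POSITIVE, UNGRADABLE, DLADecision)


def make_cohort(rows):
    """rows: (image_id, patient_id, gradable, score)"""
    recs = []
    for iid, pid, gradable, score in rows:
        n = len([r for r in recs if r["patient_id"] == pid])
        recs.append(dict(image_id=iid, patient_id=pid, visit_year=2009,
                         eye="left" if n < 2 else "right",
                         field="F1" if n % 2 == 0 else "F2",
                         true_grade="R0", gradable=gradable,
                         score=score))
    return Cohort(pd.DataFrame(recs))


def decide_all(cohort, threshold=0.485):
    return dla_decide_cohort(cohort, ClassifierModel(threshold=threshold))


def test_decision_rule_and_boundary():
    model = ClassifierModel(threshold=0.485)

    def img(score, gradable=True):
        return ImageRecord("i", "P1", 2009, "left", "F1", GradeLabel.R0,
                           gradable, score)

    assert dla_decide(img(0.485), model) == DLADecision.POSITIVE
    assert dla_decide(img(0.2), model) == DLADecision.NEGATIVE
    assert dla_decide(img(None, gradable=False), model) \
        == DLADecision.UNGRADABLE


def test_selection_reasons_direct_rule_application():
    cohort = make_cohort([
        ("a1", "A", True, 0.9),    # DLA positive
        ("a2", "A", True, 0.1),    # negative, same patient
        ("a3", "A", False, None),  # ungradable, same patient
        ("b1", "B", True, 0.2),
        ("b2", "B", True, 0.3),
    ])
    sel = select_for_review(cohort, decide_all(cohort),
                            TriageConfig(qa_fraction=0.0))
    got = {s.image_id: s.reason for s in sel}
    assert got == {"a1": REASON_POSITIVE, "a2": REASON_LINKED,
                   "a3": REASON_LINKED}


def test_no_positives_no_qa_gives_empty_selection():
    cohort = make_cohort([("a1", "A", True, 0.1), ("b1", "B", True, 0.2)])
    sel = select_for_review(cohort, decide_all(cohort),
                            TriageConfig(qa_fraction=0.0))
    assert sel == []


def test_reason_priority_positive_beats_linked():
    cohort = make_cohort([("a1", "A", True, 0.9), ("a2", "A", True, 0.95)])
    sel = select_for_review(cohort, decide_all(cohort),
                            TriageConfig(qa_fraction=0.0))
    assert all(s.reason == REASON_POSITIVE for s in sel)
    assert len(sel) == len({s.image_id for s in sel}) == 2


def test_qa_sample_size_and_pool_exclusions():
    rows = [("a1", "A", True, 0.9)]
    rows += [(f"n{i}", f"N{i}", True, 0.1) for i in range(100)]
    cohort = make_cohort(rows)
    sel = select_for_review(cohort, decide_all(cohort),
                            TriageConfig(qa_fraction=0.05, rng_seed=3))
    qa = [s for s in sel if s.reason == REASON_QA]
    assert len(qa) == 5  # 5% of the 100 remaining negatives
    assert all(s.image_id.startswith("n") for s in qa)


def test_qa_count_override_and_pool_overflow():
    rows = [(f"n{i}", f"N{i}", True, 0.1) for i in range(10)]
    cohort = make_cohort(rows)
    sel = select_for_review(cohort, decide_all(cohort),
                            TriageConfig(qa_count_override=7, rng_seed=1))
    assert sum(s.reason == REASON_QA for s in sel) == 7
    with pytest.raises(ValueError):
        select_for_review(cohort, decide_all(cohort),
                          TriageConfig(qa_count_override=11))


def test_qa_never_samples_ungradable():
    rows = [("a1", "A", True, 0.9)]
    rows += [(f"u{i}", f"U{i}", False, None) for i in range(20)]
    cohort = make_cohort(rows)
    sel = select_for_review(cohort, decide_all(cohort),
                            TriageConfig(qa_fraction=1.0, rng_seed=2))
    assert not any(s.image_id.startswith("u") and s.reason == REASON_QA
                   for s in sel)


def test_qa_monotone_in_fraction(baseline_cohort, model953):
    decisions = dla_decide_cohort(baseline_cohort, model953)
    prev: set = set()
    for frac in (0.0, 0.02, 0.05, 0.10, 0.5):
        sel = select_for_review(baseline_cohort, decisions,
                                TriageConfig(qa_fraction=frac, rng_seed=9))
        ids = {s.image_id for s in sel}
        assert prev <= ids
        prev = ids


def test_selection_deterministic_under_seed(baseline_cohort, model953):
    decisions = dla_decide_cohort(baseline_cohort, model953)
    cfg = TriageConfig(qa_fraction=0.05, rng_seed=4)
    a = select_for_review(baseline_cohort, decisions, cfg)
    b = select_for_review(baseline_cohort, decisions, cfg)
    assert a == b


def test_decision_partition_counts(baseline_cohort, model953):
    decisions = dla_decide_cohort(baseline_cohort, model953)
    counts = decisions.value_counts()
    assert counts.sum() == baseline_cohort.n_images
    assert set(counts.index) <= {POSITIVE, NEGATIVE, UNGRADABLE}


def test_assemble_pass_through_and_correction():
    cohort = make_cohort([
        ("a1", "A", True, 0.9),   # DLA FP (truth R0), reviewed
        ("b1", "B", True, 0.1),   # unselected negative
    ])
    decisions = decide_all(cohort)
    sel = select_for_review(cohort, decisions, TriageConfig(qa_fraction=0.0))
    ref = {"a1": GradeLabel.R0}  # perfect grader says non-referable
    result = assemble_workflow_result(cohort, decisions, sel, ref)
    f = result.frame.set_index("image_id")
    assert f.loc["a1", "final_label"] == NEGATIVE
    assert f.loc["a1", "label_source"] == "HUMAN"
    assert f.loc["b1", "final_label"] == NEGATIVE
    assert f.loc["b1", "label_source"] == "DLA"


def test_assemble_requires_reference_for_selected():
    cohort = make_cohort([("a1", "A", True, 0.9)])
    decisions = decide_all(cohort)
    sel = select_for_review(cohort, decisions, TriageConfig(qa_fraction=0.0))
    with pytest.raises(ValueError):
        assemble_workflow_result(cohort, decisions, sel, {})


def test_full_review_with_perfect_graders_recovers_truth(model953):
    """qa_fraction=1 plus perfect graders: final labels agree with truth
    on every gradable image of a ~200-image cohort."""
    params = CohortParams(n_patients=50, years=[2009],
                          p_referable_patient=0.3, rng_seed=31)
    cohort = simulate_cohort(params, model953)
    decisions = dla_decide_cohort(cohort, model953)
    sel = select_for_review(cohort, decisions,
                            TriageConfig(qa_fraction=1.0, rng_seed=1))
    truth = {r.image_id: r.true_grade for r in cohort.records()}
    ref = {s.image_id: truth[s.image_id] for s in sel
           if s.image_id in truth and cohort.frame.set_index("image_id")
           .loc[s.image_id, "gradable"]}
    result = assemble_workflow_result(cohort, decisions, sel, ref)
    f = result.frame.set_index("image_id")
    for rec in cohort.records():
        if rec.gradable:
            want = POSITIVE if referable(rec.true_grade) else NEGATIVE
            assert f.loc[rec.image_id, "final_label"] == want


def test_mismatched_decision_index_rejected(baseline_cohort, model953):
    decisions = dla_decide_cohort(baseline_cohort, model953).iloc[:-1]
    with pytest.raises(ValueError):
        select_for_review(baseline_cohort, decisions, TriageConfig())
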