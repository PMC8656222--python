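"""Accuracy layer: confusion, kappa, ROC/AUC, and their oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from drtriage import (ConfusionMatrix2x2, accuracy_sens_spec,
                      cicchetti_allison_weights, confusion, roc_auc,
                      weighted_kappa)
from conftest import cohen_kappa_2x2, mann_whitney_auc

TABLE2 = ConfusionMatrix2x2(tp=191, fp=289, fn=7, tn=2117)


# ---- confusion ---------------------------------------------------------

def test_identical_vectors_have_no_errors():
    dec = np.array(["POSITIVE", "NEGATIVE", "POSITIVE"])
    cm = confusion(dec, dec)
    assert (cm.fp, cm.fn) == (0, 0)
    assert cm.n == 3


def test_reviewed_baseline_counts_recovered_from_labels(rng):
    """Rebuild the published reviewed-set confusion matrix from expanded
    per-image label vectors."""
    dec = (["POSITIVE"] * (191 + 289)) + (["NEGATIVE"] * (7 + 2117))
    ref = ([True] * 191 + [False] * 289) + ([True] * 7 + [False] * 2117)
    order = rng.permutation(len(dec))
    cm = confusion(np.array(dec)[order], np.array(ref)[order])
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (191, 289, 7, 2117)


def test_complementing_decisions_swaps_cells():
    dec = np.array([True, True, False, False, True])
    ref = np.array([True, False, True, False, False])
    cm = confusion(dec, ref)
    swapped = confusion(~dec, ref)
    assert (swapped.tp, swapped.fp) == (cm.fn, cm.tn)
    assert (swapped.fn, swapped.tn) == (cm.tp, cm.fp)


def test_series_inputs_align_on_index_and_mismatch_raises():
    dec = pd.Series([True, False], index=["a", "b"])
    ref = pd.Series([False, True], index=["b", "a"])
    cm = confusion(dec, ref)  # aligns on labels: a agrees, b agrees
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)
    with pytest.raises(ValueError):
        confusion(dec, pd.Series([True], index=["a"]))


# ---- accuracy / sensitivity / specificity ------------------------------

def test_reviewed_baseline_metrics():
    acc = accuracy_sens_spec(TABLE2)
    assert acc.accuracy == pytest.approx(2308 / 2604)
    assert round(acc.accuracy, 3) == 0.886
    assert acc.specificity == pytest.approx(2117 / 2406)
    assert round(acc.specificity, 3) == 0.880
    assert acc.sensitivity == pytest.approx(191 / 198)


def test_perfect_matrix_all_ones():
    acc = accuracy_sens_spec(ConfusionMatrix2x2(1, 0, 0, 1))
    assert acc == (1.0, 1.0, 1.0)


def test_zero_denominators_reported_absent():
    acc = accuracy_sens_spec(ConfusionMatrix2x2(tp=0, fp=3, fn=0, tn=5))
    assert acc.sensitivity is None
    assert acc.specificity == pytest.approx(5 / 8)


def test_sens_spec_invariant_to_prevalence(rng):
    """Resampling the negative class changes accuracy but not the
    class-conditional rates."""
    cm = ConfusionMatrix2x2(tp=80, fp=50, fn=20, tn=950)
    thinned = ConfusionMatrix2x2(tp=80, fp=5, fn=20, tn=95)
    a, b = accuracy_sens_spec(cm), accuracy_sens_spec(thinned)
    assert a.sensitivity == b.sensitivity
    assert a.specificity == pytest.approx(b.specificity)
    assert a.accuracy != b.accuracy


# ---- weighted kappa ----------------------------------------------------

def test_linear_weights_form():
    w = cicchetti_allison_weights(5)
    assert w[0, 0] == 1.0
    assert w[0, 4] == 0.0
    assert w[1, 3] == pytest.approx(1 - 2 / 4)
    assert np.allclose(w, w.T)


def test_reviewed_baseline_agreement_kappa():
    res = weighted_kappa(TABLE2.as_table())
    assert round(res.kappa, 3) == 0.511
    # large-sample CI reproduces the published interval to 3 decimals
    assert round(res.ci_low, 3) == 0.465
    assert round(res.ci_high, 3) == 0.557


def test_perfect_agreement_and_chance_only():
    assert weighted_kappa(np.diag([5, 9, 3])).kappa == pytest.approx(1.0)
    # counts proportional to margin products -> chance-only agreement
    row = np.array([0.2, 0.5, 0.3])
    col = np.array([0.4, 0.4, 0.2])
    table = np.outer(row, col) * 1000
    assert weighted_kappa(table).kappa == pytest.approx(0.0, abs=1e-12)


@given(a=st.integers(0, 50), b=st.integers(0, 50),
       c=st.integers(0, 50), d=st.integers(1, 50))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_binary_weighted_kappa_equals_cohen_brute_force(a, b, c, d):
    table = np.array([[a, b], [c, d]], dtype=float)
    got = weighted_kappa(table).kappa
    want = cohen_kappa_2x2(a, b, c, d)
    if np.isfinite(want):
        assert got == pytest.approx(want, abs=1e-12)


def test_weighted_kappa_matches_sklearn_linear_weights(rng):
    """Independent cross-check on multi-category tables."""
    for _ in range(20):
        k = int(rng.integers(2, 6))
        r1 = rng.integers(0, k, size=400)
        r2 = np.where(rng.random(400) < 0.6, r1, rng.integers(0, k, size=400))
        table = np.zeros((k, k))
        np.add.at(table, (r1, r2), 1)
        got = weighted_kappa(table).kappa
        want = cohen_kappa_score(r1, r2, labels=np.arange(k),
                                 weights="linear")
        assert got == pytest.approx(want, abs=1e-10)


@given(scale=st.integers(1, 50))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_kappa_invariant_under_table_scaling(scale):
    base = TABLE2.as_table()
    assert weighted_kappa(base * scale).kappa \
        == pytest.approx(weighted_kappa(base).kappa, abs=1e-12)


def test_kappa_input_validation():
    with pytest.raises(ValueError):
        weighted_kappa(np.zeros((2, 3)))
    with pytest.raises(ValueError):
        weighted_kappa(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        weighted_kappa(TABLE2.as_table(), weighting="quadratic")


# ---- ROC / AUC ---------------------------------------------------------

def test_perfect_separation_auc_one():
    res = roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False],
                  n_boot=0)
    assert res.auc == pytest.approx(1.0)
    assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0


def test_four_pair_exhaustive_example():
    # positives {0.9, 0.4}, negatives {0.8, 0.2}: 3 of 4 pairs concordant
    res = roc_auc([0.9, 0.4, 0.8, 0.2], [1, 1, 0, 0], n_boot=0)
    assert res.auc == pytest.approx(3 / 4)


def test_trapezoid_auc_equals_mann_whitney_oracle(rng):
    """Random instances with heavy ties, n <= 200."""
    for _ in range(200):
        n_pos = int(rng.integers(1, 100))
        n_neg = int(rng.integers(1, 100))
        # coarse grid of score values forces ties
        pos = rng.integers(0, 10, n_pos) / 10.0
        neg = rng.integers(0, 10, n_neg) / 10.0
        scores = np.concatenate([pos, neg])
        y = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
        res = roc_auc(scores, y, n_boot=0)
        assert res.auc == pytest.approx(mann_whitney_auc(pos, neg),
                                        abs=1e-12)


def test_youden_cutoff_tie_break_prefers_smallest():
    # interleaved scores: J = 0.5 at both cutoff 0.9 and cutoff 0.2;
    # the smaller (sensitivity-favouring) cutoff must win
    res = roc_auc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0], n_boot=0)
    assert res.cutoff == pytest.approx(0.2)


def test_bootstrap_ci_brackets_point_estimate(rng):
    pos = rng.normal(1.2, 1, 300)
    neg = rng.normal(0, 1, 300)
    scores = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(300, bool), np.zeros(300, bool)])
    res = roc_auc(scores, y, n_boot=200, seed=5)
    assert res.ci_low <= res.auc <= res.ci_high
    res2 = roc_auc(scores, y, n_boot=200, seed=5)
    assert (res.ci_low, res.ci_high) == (res2.ci_low, res2.ci_high)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [True, True], n_boot=0)
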