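"""Diagnostic-accuracy statistics.

Implements the accuracy layer of the screening evaluation: the 2x2
confusion matrix of automated decisions against the human reference
standard, sensitivity / specificity / accuracy, the empirical ROC curve
with trapezoidal AUC and Youden-optimal cutoff, and the Cicchetti-Allison
(linear-weight) weighted kappa with its large-sample confidence interval.

A note on study design: when these statistics are computed on the
triage-reviewed subset only (as a partial-verification evaluation does),
automated negatives are under-represented, so the reviewed-subset
specificity is systematically below the full-cohort value — verification
bias. Both evaluation surfaces are exposed; the test-suite asserts the
direction of the bias on calibrated simulations.

Weighted kappa: for a k x k agreement table with cell proportions p_ij and
margins p_i., p_.j, linear disagreement weights w_ij = 1 - |i-j|/(k-1),

    kappa_w = (sum w_ij p_ij - sum w_ij p_i. p_.j)
              / (1 - sum w_ij p_i. p_.j)

which reduces to unweighted Cohen's kappa at k = 2. The standard error is
the classical large-sample form for weighted kappa (Fleiss, Cohen &
Everitt), giving a Wald 95% CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .rng import substream

__all__ = ["ConfusionMatrix2x2", "AccSensSpec", "KappaResult", "AucResult",
           "confusion", "accuracy_sens_spec", "weighted_kappa",
           "cicchetti_allison_weights", "roc_auc"]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """TP/FP/FN/TN of binary automated decisions vs the reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_table(self) -> np.ndarray:
        """2x2 agreement table, rows = test (pos, neg), cols = reference."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)


class AccSensSpec(NamedTuple):
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


class KappaResult(NamedTuple):
    kappa: float
    se: float
    ci_low: float
    ci_high: float


class AucResult(NamedTuple):
    auc: float
    ci_low: float | None
    ci_high: float | None
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def confusion(decisions, reference, positive_def: str = "POSITIVE",
              ) -> ConfusionMatrix2x2:
    """Cross-tabulate binary decisions against reference referable status.

    Parameters
    ----------
    decisions
        Per-image automated labels; positive where equal to *positive_def*
        (booleans are accepted directly).
    reference
        Per-image reference referable status (boolean) or labels matching
        *positive_def*. If both inputs are pandas Series they are aligned
        on their index and must cover the same image set.
    """
    if isinstance(decisions, pd.Series) and isinstance(reference, pd.Series):
        if set(decisions.index) != set(reference.index):
            raise ValueError("decisions and reference cover different images")
        reference = reference.reindex(decisions.index)
    d = np.asarray(decisions)
    r = np.asarray(reference)
    if d.shape != r.shape:
        raise ValueError("decisions and reference differ in length")
    dp = d if d.dtype == bool else (d == positive_def)
    rp = r if r.dtype == bool else (r == positive_def)
    tp = int(np.sum(dp & rp))
    fp = int(np.sum(dp & ~rp))
    fn = int(np.sum(~dp & rp))
    tn = int(np.sum(~dp & ~rp))
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy_sens_spec(cm: ConfusionMatrix2x2) -> AccSensSpec:
    """Accuracy, sensitivity, specificity; a ratio with a zero denominator
    is reported as None rather than 0."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.n
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    return AccSensSpec(accuracy=acc, sensitivity=sens, specificity=spec)


def cicchetti_allison_weights(k: int) -> np.ndarray:
    """Linear agreement weights w_ij = 1 - |i - j| / (k - 1)."""
    if k < 2:
        raise ValueError("need at least a 2x2 table")
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def weighted_kappa(table, weighting: str = "cicchetti_allison",
                   conf_level: float = 0.95) -> KappaResult:
    """Weighted kappa with large-sample SE and Wald CI.

    *table* is a k x k array of agreement counts (rows: rater 1, columns:
    rater 2, same category order). Only Cicchetti-Allison (linear)
    weighting is offered; at k = 2 the statistic equals unweighted Cohen's
    kappa.
    """
    if weighting != "cicchetti_allison":
        raise ValueError(f"unknown weighting: {weighting!r}")
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    n = t.sum()
    if n <= 0:
        raise ValueError("agreement table is empty")
    if np.any(t < 0):
        raise ValueError("agreement counts must be non-negative")
    k = t.shape[0]
    w = cicchetti_allison_weights(k)
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po_w = float((w * p).sum())
    pe_w = float((w * np.outer(row, col)).sum())
    if pe_w >= 1.0:
        # degenerate: all mass in one weighted-agreement cell
        return KappaResult(kappa=1.0, se=0.0, ci_low=1.0, ci_high=1.0)
    kappa = (po_w - pe_w) / (1.0 - pe_w)

    # Fleiss-Cohen-Everitt large-sample variance
    wbar_row = w @ col           # \bar w_{i.} under the column margins
    wbar_col = row @ w           # \bar w_{.j} under the row margins
    term = w - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - kappa)
    var = ((p * term**2).sum() - (kappa - pe_w * (1.0 - kappa))**2) \
        / (n * (1.0 - pe_w)**2)
    se = math.sqrt(max(var, 0.0))
    from scipy.stats import norm
    z = norm.ppf(0.5 + conf_level / 2.0)
    return KappaResult(kappa=float(kappa), se=se,
                       ci_low=float(kappa - z * se),
                       ci_high=float(kappa + z * se))


def roc_auc(scores, reference_status, *, n_boot: int = 2000,
            seed: int = 0, conf_level: float = 0.95) -> AucResult:
    """Empirical ROC analysis.

    AUC is the trapezoidal area under the empirical ROC curve (identical
    to the tie-corrected Mann-Whitney U statistic divided by n_pos*n_neg).
    The optimal cutoff maximises Youden's J = sensitivity + specificity -
    1; among tied maximisers the smallest cutoff is returned (the
    sensitivity-favouring choice for a screening setting). The CI is a
    seeded stratified percentile bootstrap; pass ``n_boot=0`` to skip it.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(reference_status, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and reference differ in length")
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative")

    fpr, tpr, thr = _roc_curve(y, s)
    auc = float(_trapezoid_auc(fpr, tpr))

    j = tpr - fpr
    best = j == j.max()
    # thresholds are decreasing; the last tied maximiser is the smallest
    i = int(np.flatnonzero(best)[-1])
    cutoff = float(thr[i])
    if not math.isfinite(cutoff):  # the (0,0) corner carries an inf cutoff
        finite = np.flatnonzero(best & np.isfinite(thr))
        i = int(finite[-1]) if finite.size else 1
        cutoff = float(thr[i])

    ci_low = ci_high = None
    if n_boot > 0:
        rng = substream(seed, "auc_bootstrap")
        pos = s[y]
        neg = s[~y]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            bs = np.concatenate([bp, bn])
            by = np.concatenate([np.ones(pos.size, bool),
                                 np.zeros(neg.size, bool)])
            bf, bt, _ = _roc_curve(by, bs)
            reps[b] = _trapezoid_auc(bf, bt)
        alpha = (1.0 - conf_level) / 2.0
        ci_low = float(np.quantile(reps, alpha))
        ci_high = float(np.quantile(reps, 1.0 - alpha))

    return AucResult(auc=auc, ci_low=ci_low, ci_high=ci_high, cutoff=cutoff,
                     sens_at_cutoff=float(tpr[i]),
                     spec_at_cutoff=float(1.0 - fpr[i]))
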