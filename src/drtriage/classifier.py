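"""Stochastic stand-in for the deep-learning grader's continuous output.

The automated grader is modelled as a continuous score in [0, 1] — the
predicted probability that an image shows referable DR — drawn from one of
two conditional score families:

``binormal``
    A latent Gaussian signal-detection model: latent values are
    N(mu_neg, 1) for non-referable images and N(mu_neg + d, 1) for
    referable ones, mapped to [0, 1] by the logistic function. Because the
    logistic map is strictly monotone, the ROC (and hence the AUC) of the
    scores equals that of the latents, and the AUC has the closed form

        AUC = Phi(d / sqrt(2)),

    so a target AUC is hit exactly with d = sqrt(2) * Phi^-1(AUC).

``beta``
    Scores live natively on [0, 1]: Beta(a0, b0) for non-referable images
    and Beta(kappa * m, kappa * (1 - m)) for referable ones; the referable
    mean m is solved numerically so the model AUC equals the target.

The model also carries the deployment operating point: images with a score
at or above ``threshold`` are called positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit, logit

__all__ = ["ClassifierModel", "calibrate_classifier", "DEFAULT_THRESHOLD"]

#: Operating cutoff on the probability scale (Youden-optimal point of the
#: deployed model this package emulates).
DEFAULT_THRESHOLD = 0.485

#: Default false-positive rate of the operating point among non-referable
#: images. Anchors the negative score distribution so that, at realistic
#: (~1%) image-level prevalence, the overall flag rate lands in the
#: 1.3-1.7% range a general screening population produces.
DEFAULT_FPR_AT_THRESHOLD = 0.009


@dataclass(frozen=True)
class ClassifierModel:
    """Conditional score distributions plus an operating threshold.

    Parameters
    ----------
    family
        ``"binormal"`` or ``"beta"``.
    threshold
        Positive-call cutoff on the score scale, in (0, 1).
    mu_neg, separation
        Binormal family: latent mean of the non-referable class and the
        latent shift of the referable class (both latents have unit SD).
    a_neg, b_neg, conc_pos, mean_pos
        Beta family: non-referable shape parameters, and the referable
        class's concentration and mean (shape = conc*mean, conc*(1-mean)).
    """

    family: str = "binormal"
    threshold: float = DEFAULT_THRESHOLD
    # binormal parameters
    mu_neg: float = -2.43
    separation: float = 2.37
    # beta parameters
    a_neg: float = 1.2
    b_neg: float = 25.0
    conc_pos: float = 4.0
    mean_pos: float = 0.75

    def __post_init__(self) -> None:
        if self.family not in ("binormal", "beta"):
            raise ValueError(f"unknown score family: {self.family!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    # ---- closed-form / numeric characteristics -------------------------

    def analytic_auc(self) -> float:
        """Model AUC: closed form for binormal, numeric for beta."""
        if self.family == "binormal":
            return float(stats.norm.cdf(self.separation / np.sqrt(2.0)))
        f_pos = stats.beta(self.conc_pos * self.mean_pos,
                           self.conc_pos * (1.0 - self.mean_pos))
        f_neg = stats.beta(self.a_neg, self.b_neg)
        val, _ = integrate.quad(lambda x: f_pos.pdf(x) * f_neg.cdf(x), 0.0, 1.0)
        return float(val)

    def analytic_sensitivity(self) -> float:
        """P(score >= threshold | referable)."""
        if self.family == "binormal":
            t = logit(self.threshold)
            return float(stats.norm.sf(t - self.mu_neg - self.separation))
        return float(stats.beta.sf(self.threshold,
                                   self.conc_pos * self.mean_pos,
                                   self.conc_pos * (1.0 - self.mean_pos)))

    def analytic_fpr(self) -> float:
        """P(score >= threshold | non-referable)."""
        if self.family == "binormal":
            t = logit(self.threshold)
            return float(stats.norm.sf(t - self.mu_neg))
        return float(stats.beta.sf(self.threshold, self.a_neg, self.b_neg))

    # ---- sampling ------------------------------------------------------

    def sample(self, is_referable: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """Draw one score in [0, 1] per image given referable status."""
        is_referable = np.asarray(is_referable, dtype=bool)
        n = is_referable.size
        if self.family == "binormal":
            latent = rng.standard_normal(n) + self.mu_neg
            latent[is_referable] += self.separation
            return expit(latent)
        scores = rng.beta(self.a_neg, self.b_neg, size=n)
        n_pos = int(is_referable.sum())
        if n_pos:
            scores[is_referable] = rng.beta(
                self.conc_pos * self.mean_pos,
                self.conc_pos * (1.0 - self.mean_pos), size=n_pos)
        return scores

    def with_threshold(self, threshold: float) -> "ClassifierModel":
        return replace(self, threshold=threshold)


def calibrate_classifier(target_auc: float, family: str = "binormal", *,
                         threshold: float = DEFAULT_THRESHOLD,
                         fpr_at_threshold: float = DEFAULT_FPR_AT_THRESHOLD,
                         ) -> ClassifierModel:
    """Build a score model whose analytic AUC equals *target_auc*.

    For the binormal family the separation is the exact inversion
    d = sqrt(2) * Phi^-1(AUC), and the negative-class latent mean is placed
    so the operating point has false-positive rate ``fpr_at_threshold``.
    For the beta family the referable-class mean is solved numerically.

    Raises
    ------
    ValueError
        If ``target_auc`` is outside the open interval (0.5, 1).
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must lie in [0.5, 1)")
    if family == "binormal":
        d = float(np.sqrt(2.0) * stats.norm.ppf(target_auc))
        mu_neg = float(logit(threshold) - stats.norm.isf(fpr_at_threshold))
        return ClassifierModel(family="binormal", threshold=threshold,
                               mu_neg=mu_neg, separation=d)
    if family == "beta":
        base = ClassifierModel(family="beta", threshold=threshold)

        def auc_gap(m: float) -> float:
            return replace(base, mean_pos=m).analytic_auc() - target_auc

        m = optimize.brentq(auc_gap, 0.05, 0.995, xtol=1e-10)
        return replace(base, mean_pos=float(m))
    raise ValueError(f"unknown score family: {family!r}")
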