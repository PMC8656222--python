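"""Diagnostic-accuracy layer on a reviewed screening set.

Takes the confusion matrix of automated decisions versus the adjudicated
human reference on a reviewed baseline set (191 true positives, 289 false
positives, 7 false negatives, 2,117 true negatives) and computes accuracy,
sensitivity, specificity and the Cicchetti-Allison weighted kappa with its
95% confidence interval.
"""

from drtriage import ConfusionMatrix2x2, accuracy_sens_spec, weighted_kappa

cm = ConfusionMatrix2x2(tp=191, fp=289, fn=7, tn=2117)
acc = accuracy_sens_spec(cm)
kap = weighted_kappa(cm.as_table())

print(f"reviewed images        : {cm.n}")
print(f"accuracy               : {acc.accuracy:.3f}")
print(f"sensitivity            : {acc.sensitivity:.3f}")
print(f"specificity            : {acc.specificity:.3f}")
print(f"weighted kappa (linear): {kap.kappa:.3f} "
      f"(95% CI {kap.ci_low:.3f}-{kap.ci_high:.3f})")
print()
print("Accuracy is the fraction of reviewed images the automated grader")
print("called correctly; kappa ~0.5 means moderate chance-corrected")
print("agreement — the automated grader over-calls referable disease,")
print("which is the safe direction for a triage filter.")
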