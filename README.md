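# drtriage

Simulation and evaluation of **semi-automated diabetic-retinopathy (DR)
screening workflows**, in which a deep-learning classifier grades every
fundus photograph and human graders regrade only a flagged high-risk
subset.

Screening programmes photograph both eyes of each participant in two
fields (F1 disc-centred, F2 macula-centred) at annual visits. A trained
classifier assigns each image a probability of *referable DR*
(NHS grades R2 / R3a / R3s — pre-proliferative disease or worse) and calls
it positive, negative, or ungradable. Human graders then review:

1. every automated **positive**;
2. **all other images of any patient with a positive** (even if negative
   or ungradable) — disease is a patient property, so the whole patient is
   re-examined;
3. a random **~5% quality-assurance sample** of the remaining negatives.

Reviewed images receive an adjudicated reference grade: a panel of trained
graders grades independently, and on any disagreement about referable
status a senior ophthalmologist's diagnosis is conclusive. Images the
classifier cleared and the QA sample did not touch keep their automated
label — that is where the time and money are saved, and where the risk
(unreviewed false negatives, verification bias) lives. This package exists
to quantify both sides.

## What is in the box

| module | contents |
| --- | --- |
| `drtriage.cohort` | seeded synthetic longitudinal cohort generator (truth at eye-year level, gradability, scores) |
| `drtriage.classifier` | binormal / beta score models; exact AUC calibration `d = √2·Φ⁻¹(AUC)`; operating-point closed forms |
| `drtriage.image_prep` | fundus normalisation: 90% centre-crop → 299×299 resize → local-average subtraction onto 50% gray |
| `drtriage.triage` | automated decisions, review selection with reason priority, final-label assembly |
| `drtriage.adjudication` | independent panel + senior tie-break reference standard |
| `drtriage.metrics` | confusion matrix, sensitivity/specificity/accuracy, trapezoid ROC-AUC with Youden cutoff and bootstrap CI, Cicchetti–Allison weighted κ with large-sample CI |
| `drtriage.cost` | time/money comparison of fully-human, fully-automated and semi-automated grading |
| `drtriage.pipeline` | `run_pipeline(RunConfig)`: simulate → triage → adjudicate → metrics → cost, bit-reproducible run directories |

The statistics at the core, in standard notation: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n; AUC as the
trapezoidal area under the empirical ROC (≡ tie-corrected Mann–Whitney
statistic); weighted kappa

κ_W = (Σ w_ij p_ij − Σ w_ij p_i· p_·j) / (1 − Σ w_ij p_i· p_·j),
  w_ij = 1 − |i−j|/(k−1),

which reduces to Cohen's κ for the binary referable endpoint; and the
semi-automated cost T_semi = N·t_machine + n_reviewed·t_human, with
savings 1 − semi/fully-human per dimension.

## Worked example

```bash
python examples/reconstruct_reviewed_metrics.py
```

```
reviewed images        : 2604
accuracy               : 0.886
sensitivity            : 0.965
specificity            : 0.880
weighted kappa (linear): 0.511 (95% CI 0.465-0.557)
```

A reviewed screening set of 2,604 images (TP=191, FP=289, FN=7, TN=2,117):
the automated grader calls 88.6% of reviewed images correctly, misses 7 of
198 referable images, and over-calls disease (289 false positives) — the
safe direction for a triage filter, since every positive is re-examined by
a human. κ≈0.51 is moderate chance-corrected agreement.

Running the full synthetic workflow
(`python examples/simulate_and_run_workflow.py`) prints, for a
2,000-patient cohort (8,000 images):

```
automated positive  : 118 (1.48%)
flagged for review  : 771 (118 positive, 282 linked, 371 QA)
reviewed-subset  sens 0.542  spec 0.893  AUC 0.902  kappa 0.367
full cohort truth sens 0.413  spec 0.991  AUC 0.930
cost saving vs fully human: 90.5%
```

Note the gap between the reviewed-subset and truth-based specificity —
verification bias, visible here because the simulation knows the truth.

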