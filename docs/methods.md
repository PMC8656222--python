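# Methods

## The workflow being modelled

A triage-style screening programme grades every fundus photograph with an
automated classifier and sends a high-risk subset to human graders:
automated positives, all other images of patients with a positive, and a
random quality-assurance (QA) sample of automated negatives. Reviewed
images get an adjudicated human reference grade; unreviewed images keep
the automated label. The package simulates this end to end and computes
the diagnostic-accuracy and cost layers.

## Synthetic cohort

The generator emulates the *statistical structure* of a two-field
(F1 disc-centred, F2 macula-centred), two-eye annual screening cohort; it
does not simulate retinal lesions, camera physics, or covariates.

- **Truth at the eye-year level.** Retinopathy status is a property of an
  eye, so both fields of an eye-year share one true grade. A patient
  *ever* develops referable DR with probability `p_referable_patient`
  (default 0.015 — a general, non-diabetes-enriched population); onset is
  uniform over the simulated years; both eyes are affected with
  probability 0.4, otherwise one random eye. Referable eye-years draw
  their category R2:R3a:R3s = 80:15:5 (screening populations are
  dominated by pre-proliferative disease); non-referable eye-years draw
  R0:R1 = 85:15. With monotone progression (default) referable status
  persists once present; the toggle exists for sensitivity analyses.
- **Gradability.** Each image is independently ungradable with
  probability `p_ungradable` (default 0.0223, the ungradable fraction
  seen in large primary-care fundus datasets). Independence from disease
  status is an assumption — real ungradable images may hide more disease;
  the knob is per-image so dependence can be added by stratified runs.
- **Scores.** Gradable images draw a score from the classifier model
  conditional on the eye-year's referable status. Ungradable images carry
  no score.
- **Seeding.** One integer seed; named substreams ("truth", "quality",
  "scores", "qa_sampling", "adjudication", …) derived via
  `SeedSequence(seed, spawn_key=crc32(name))`, so changing grader noise
  never perturbs the cohort draw and reruns are byte-identical.

What passing tests on this generator show about real data: that the
*procedures* (selection rules, adjudication, estimators, cost accounting)
behave as specified under known truth. They do not validate the
classifier itself, grader correlation structure, or any clinical claim.

## Classifier score model

Default family is binormal on a latent scale: non-referable latents
N(mu_neg, 1), referable latents N(mu_neg + d, 1), mapped to [0, 1] by the
logistic function (monotone, so ROC/AUC are preserved). Calibration to a
target AUC is exact: d = √2·Φ⁻¹(AUC). A beta family (scores natively in
[0, 1]) is offered with numeric calibration of the referable-class mean.

The operating threshold defaults to 0.485 on the probability scale. The
spec of a published ROC fixes AUC and threshold but not the score
*location*; we anchor `mu_neg` so that the analytic false-positive rate at
the threshold is 0.9%. At ~1% image-level prevalence this puts the
automated flag rate near 1.5%, the range reported for deployed DR triage
on general populations, and implies a per-image sensitivity at the
threshold of ~0.50 — flag-rate accounting (TP ≈ half of flags) rather
than the ROC-derived headline sensitivity, which on a verification-biased
reviewed subset is much higher. This anchoring is the package's own
choice and is a config knob (`fpr_at_threshold`).

## Image normalisation

Centre-crop retaining 90% of each *linear* dimension (removes the
circular-mask rim symmetrically; 2000×1980 → 1800×1782, floored), then
bilinear resize to 299×299×3, then per-channel subtraction of a local
average and re-centring on 50% gray (add 128), then clamp to [0, 255].
The "local average" kernel is a convention choice: a Gaussian with
σ = out_size/30; a gain knob on the residual exists (classic fundus
preprocessing uses 4) but defaults to 1 (plain subtraction). Crop precedes
resize. Consequences used as tests: constant images map exactly to 128,
and a constant intensity offset of the input is absorbed.

## Triage rules

- Threshold comparison is `>=` (boundary positive), fixed for
  determinism.
- Reason priority DLA_POSITIVE > PATIENT_LINKED > QA_SAMPLE; an image can
  be selected once only.
- QA sampling is without replacement from the post-linkage negative pool
  (linked negatives are not re-sampled), implemented as a fixed seeded
  permutation truncated at k = round(qa_fraction · pool); this makes the
  selection monotone in `qa_fraction`. `qa_count_override` supports
  programmes that audit a fixed count rather than a fixed fraction.
- Ungradable images are never QA-sampled (they cannot be graded) but are
  pulled in by patient linkage by default.
- Selection is image-level; patient-level referral semantics are
  reported, not used for accuracy metrics.

## Adjudication

Panel members grade independently given truth (no correlation term — a
known simplification; correlated graders would lower consensus accuracy).
Consensus requires unanimity on referable status; the consensus category
is the panel's modal grade with ties broken toward the less severe grade.
The senior grader is error-free by default because the workflow treats the
senior diagnosis as conclusive; with a perfect senior the reference is
wrong only when the panel is unanimously wrong, P(wrong) = (1−p)^k.

## Accuracy layer

- Ungradable images are excluded from every accuracy computation.
- Sens/spec/accuracy with zero denominators reported as absent, never 0.
- AUC is the trapezoid area under the empirical ROC (ties at ½,
  equivalent to Mann–Whitney); the optimal cutoff maximises Youden's J
  with ties broken toward the smallest cutoff (favouring sensitivity, the
  right bias for screening). The AUC CI is a seeded stratified percentile
  bootstrap (default 2,000 replicates; pipeline default 500).
- Weighted kappa uses Cicchetti–Allison linear weights; at k = 2 it
  equals Cohen's κ. The CI uses the classical large-sample SE for
  weighted kappa (Fleiss–Cohen–Everitt form); on the reviewed baseline
  table it reproduces the published 0.465–0.557 interval, but the
  published CI method is unstated, so agreement is a check, not a
  guarantee.
- Two evaluation surfaces are always distinguished: *reviewed subset vs
  adjudicated reference* (what a deployment can measure — subject to
  verification bias, since negatives are under-verified) and *full cohort
  vs simulated truth* (available only in simulation). The suite asserts
  the bias direction: reviewed-subset specificity ≤ full-cohort
  specificity.
- A multi-year pooled AUC can aggregate pooled scores or average yearly
  AUCs; both are reported (`auc` on the pooled row and
  `auc_mean_of_years`).

## Cost model

Fully human: N·t_human minutes and N·c_human dollars. Fully automated:
N·t_machine minutes, machine marginal cost zero by default (running a
trained model is cheap; development cost is out of scope). Semi-automated:
machine over all N plus human over the n_reviewed flagged images. Savings
are 1 − semi/fully-human per dimension, from full-precision totals.
`rounded_savings()` additionally recomputes the savings from per-image
means rounded to printed precision (time 2 dp of a minute for the
semi-automated mean, 3 dp for the human mean; cost 3 dp), because
published comparisons quote per-image means and the two routes differ by
rounding alone (≈75.5% vs 74.2% time saving, 90.1% vs 89.8% cost saving
on the follow-up workload). Totals keep full precision internally;
rounding happens only at report emission.

## Numerical and design choices

- Scale of default experiments: tests use cohorts of 50–2,000 patients
  (up to 24,000 images) and Monte-Carlo sizes of 10⁴–2×10⁵ draws, chosen
  so every stochastic check sits at ≥3-SE separation while the whole
  suite runs in seconds.
- Stochastic assertions use 3-SE bands (binomial or Hanley–McNeil for
  AUC); clustered quantities (image-level prevalence with 4–8 images per
  patient) widen the band by a conservative design-effect factor.
- AUC target 0.5 is accepted in calibration (separation 0, the
  no-information limit); targets below 0.5 or at/above 1 are rejected.
- Degenerate kappa tables (all weighted mass concentrated, chance
  agreement 1) return κ = 1 with zero SE rather than 0/0.

## Known limitations

- No grader correlation, fatigue, or drift; no distinct trained-grader vs
  ophthalmologist tiers (a single configurable panel).
- Ungradability independent of disease by default.
- No lesion-level simulation; the image module normalises arrays but the
  classifier model never looks at pixels — scores are simulated, which is
  precisely what makes truth-based evaluation possible.
- No health-economic modelling beyond grading labour (no QALYs, referral
  costs, or discounting).
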