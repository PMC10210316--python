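# Methods

## Scope and model

The package evaluates three postoperative severity scores as predictors
of a binary poor in-hospital outcome after coronary artery bypass
grafting: VIS (hemodynamic support), VVR = VI + VIS + 10·ΔCr and
M-VVR = VI + VIS + Ccr. The statistical pipeline mirrors the standard
score-comparison design: descriptive two-group tests, per-score logistic
regression (unadjusted and adjusted), ROC/AUC with paired DeLong
contrasts, Hosmer–Lemeshow calibration, and the design-stage
two-proportion sample-size calculation.

## Score definitions and their open choices

Several ingredients of the scores are reported in the literature only at
the level of "a VIS", "a ventilation index", "a creatinine clearance";
the package fixes them as follows, each behind a configurable surface:

- **VIS weights** use the standard adult weighting (dopamine 1,
  dobutamine 1, epinephrine 100, norepinephrine 100, milrinone 10,
  vasopressin 10 000). The weight table is a single dict
  (`scores.VIS_WEIGHTS`) so alternates are testable. A converter accepts
  vasopressin in mU/kg/min.
- **VI** = RR·(PIP − PEEP)·PaCO₂/1000, the form used in the VVR
  literature.
- **Ccr** is the Cockcroft–Gault estimate on the *postoperative*
  creatinine with the 0.85 female factor — the common bedside choice,
  and the one consistent with M-VVR's single-measurement design. eGFR
  equations (CKD-EPI/MDRD) are deliberately out of scope.
- **ΔCr flooring**: a postoperative creatinine *drop* counts as zero
  renal injury rather than a score credit (`flooring="floored"`,
  default); the signed variant is available. Flooring keeps VVR ≥ 0.
- **M-VVR coefficient on Ccr** defaults to 1 (no ×10). With VIS median
  0, VI near 7 and Ccr near 90 mL/min this puts the M-VVR median near
  100, matching the published cohort's median of 99.96; a ×10
  coefficient would put it near 1000. The coefficient is exposed
  (`ccr_coefficient`) for sensitivity analyses.

Note the direction tension inherent in M-VVR: higher Ccr means *better*
renal function, yet M-VVR is used as a severity score in which higher
values predict worse outcomes. The package implements the score as
defined and leaves the interpretation to the analyst.

Scores are kept at full precision internally; 2-dp rounding appears only
in report columns.

## Synthetic cohort

`cohort.generate_frame` draws seeded cohorts whose marginals match the
published descriptive table: binary covariates at the printed
prevalences, LVEF at (12.48 %, 17.32 %, 70.20 %), age ~ N(65.39, 7.66²)
truncated to the 18–80 inclusion range (truncation pulls the realized
mean ≈ 0.5 y low), BMI ~ N(24.97, 3.22²). Weight, which the published
table lacks but Cockcroft–Gault needs, is BMI·height² with height ~
N(1.67 m, 0.08 m).

Vasoactive support is zero-inflated: with probability 0.70 all doses are
zero; otherwise a total VIS is drawn log-normal(ln 6, 0.6) and split
across drugs at fixed fractions. These two numbers were moment-matched
once to the printed quantiles (median 0, Q3 ≈ 4) and frozen. Ventilator
settings and creatinine are truncated-normal/log-normal draws whose
frozen parameters put the VVR median near 8 and the M-VVR median near
100, as printed; baseline creatinine is log-normal(ln 0.74, 0.18) with a
post/baseline ratio log-normal(ln 1.02, 0.10).

The outcome is Bernoulli with logit = intercept + β·(M-VVR, male, BMI,
hypertension, diabetes, on-pump, LVEF-moderate, LVEF-poor). Slope signs
follow the published between-group contrasts (hypertension is
*protective* in that table); the default score slope is 0.025 per M-VVR
unit, which yields an M-VVR AUC near 0.7 at the default size. The
intercept is calibrated per cohort by root-finding so the mean event
probability hits the target fraction 133/537; the realized value is
returned in the generation provenance and used as the truth in
parameter-recovery tests.

What the generator does **not** emulate:

- Covariates are sampled independently — only marginals are published.
  Consequently the derived `comorbidity` flag (OR of the six
  disease-history indicators) has prevalence ≈ 0.82 rather than the
  printed 48.8 %, which implies the real flags were correlated (or
  defined more narrowly).
- VIS, VI and Ccr are mutually independent given the draw, and the
  outcome depends on them only through M-VVR. Real data have
  within-patient correlation across organ systems, which is what gives
  VIS and VVR their own discriminative ability; in synthetic cohorts
  their AUCs are near 0.5. Passing tests therefore validate the
  *estimators*, not any clinical claim about the scores.
- Sex is a common cause of M-VVR (the 0.85 Cockcroft–Gault factor) and
  of the outcome, so zeroing only the score slope does not make M-VVR
  null — a deliberate, realistic confounding feature.

## Statistical procedures

- **Chi-square**: Pearson's Σ(O−E)²/E without continuity correction —
  the only variant that reproduces all printed categorical statistics
  (4.117, 8.889, 5.582, 5.169, 31.711 and the remaining two-level rows)
  from the printed counts. Expected counts < 1 attach a warning.
- **Welch t** (unequal variances, Welch–Satterthwaite df): the printed
  BMI statistic −2.78 matches Welch (−2.778), not the pooled-variance t
  (−2.786 → −2.79). Callable from summaries (n, mean, SD) or raw
  samples.
- **Mann-Whitney**: midrank U converted to a tie-corrected Z without
  continuity correction; heavy ties (the VIS = 0 point mass) are
  load-bearing. Exact enumeration (`mann_whitney_exact_p`) serves as the
  small-sample oracle (n₁+n₂ ≤ 12).
- **Logistic regression**: IRLS with step-halving (the log-likelihood
  never decreases), convergence at max|gradient| < 1e-8 or relative
  log-likelihood change < 1e-10, Wald covariance from the inverse
  observed information. |β| > 15 flags quasi-complete separation: the
  fit is marked non-converged and OR accessors raise instead of
  reporting nonsense. No penalization by default. LVEF enters as two
  dummies against the "normal" (largest) reference; each score is
  modelled in its own regression, matching the published table layout.
- **AUC/DeLong**: midrank AUC (equals brute-force pair counting and
  trapezoidal ROC integration); DeLong structural components give the
  single-score variance and the paired covariance; CIs are Wald,
  truncated to [0, 1], collapsing with a warning under perfect
  separation. Higher score = worse outcome is assumed throughout; no
  multiplicity adjustment across the three pairwise contrasts (a
  Bonferroni step is the analyst's choice).
- **Hosmer–Lemeshow**: equal-frequency bins on sorted predicted
  probability (default 10), ties kept in one bin and empty bins merged
  with df reduced accordingly; H = Σ(O−E)²/(E(1−E/n_g)), df = bins − 2.
  Calibration is computed on fitted probabilities from the *adjusted*
  M-VVR model by default.
- **Sample size**: the pooled-null/unpooled-alternative two-proportion z
  formula with the unweighted mean p̄, no continuity correction —
  two-sided α = 0.05 and power 0.90 reproduce the published 214 per
  group exactly (one-sided would give 174; the Fleiss continuity
  correction gives 241). Dropout inflation is ⌈n/(1−rate)⌉ → 535.
  `empirical_power` simulates the pooled z-test; note the exact power at
  n = 214 is 0.925, not 0.90 — the normal approximation is conservative
  with only ~4 vs ~20 expected events per arm.

## Problem sizes used in validation

The test suite validates marginal fidelity at n = 100 000 (3 binomial
SEs), parameter recovery over 100 cohorts of n = 50 000 (≥ 90 %
per-coefficient Wald coverage), Wald CI coverage over 500 replicates at
n = 2 000, Hosmer–Lemeshow null behavior over 1 000 replicates at
n = 2 000, a 500-replicate bootstrap and a 10 000-replicate permutation
oracle for the DeLong procedures, and exact binomial enumeration for the
power check. The pROC package (via Rscript) provides an independent
reference for the DeLong CI and paired test.

## Pipeline determinism

`run_analysis` is deterministic given (config, seed, input bytes): the
provenance artifact stores a config hash (excluding the output
directory), the input SHA-256 and the seed; wall-clock timestamps appear
only in the log stream so report files are byte-identical across reruns.

## Known limitations

- The published headline results (AUCs 0.720/0.621/0.685, adjusted ORs,
  DeLong p-values) require the original patient records, which are not
  deposited; the package reproduces the *methodology* and the printed
  summary/design numbers, not those patient-level estimates.
- The SinoSCORE comparison is not implemented (its definition is not
  public in the source material).
- Exact (enumeration) Mann-Whitney p-values are available only for tiny
  samples; cohort-scale inference uses the normal approximation.
- Firth-type separation correction is not implemented; separation is
  reported, not repaired.
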