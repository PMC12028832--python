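# Methods

This note documents the models, defaults and numerical conventions the
package implements, the design choices made where the design was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Growth-potential extrapolation

The core statistic treats the 20-week estimated fetal weight (EFW) as a
proxy for the fetus's growth potential and carries it to the third trimester
on the multiples-of-the-median (MoM) scale:

- `EFW MoM(20w) = EFW(20w) / median(GA20)`;
- `ExFW3t = EFW MoM(20w) × median(GA3t)` — the weight expected if the fetus
  kept its mid-pregnancy centile track;
- `%ExFW3t = 100 + 100·(EFW3t − ExFW3t)/ExFW3t`, computed as the
  algebraically identical `100·EFW3t/ExFW3t`.

Two exact consequences are enforced by tests: `%ExFW3t(k·x, x) = 100k` for
all positive `k, x`, and invariance of `%ExFW3t` to the units of the median
curve (the MoM cancels the scale). Eligibility windows — the mid-pregnancy
scan at week 20 ± 1, the third-trimester scan between 30+0 and 40+6 weeks —
are validated but overridable (`enforce_windows=False`) so the synthetic
module can stress-test outside them.

EFW from biometry uses the four-parameter Hadlock formula (BPD/HC/AC/FL in
cm, grams out):
`log10 EFW = 1.3596 + 0.0064·HC + 0.0424·AC + 0.174·FL + 0.00061·BPD·AC − 0.00386·AC·FL`.
This coefficient set is the standard published four-parameter variant and is
hard-coded and unit-checked; a cohort file may instead supply EFW directly.

## Reference curves

A `ReferenceCurve` is a (median, log-SD) pair over a gestational-age range;
MoM is value/median and centiles use the log-normal model
`centile = 100·Φ(ln(value/median)/log_sd)`, so the median maps to the 50th
centile exactly for every age and reference. All curves are replaceable via
JSON (polynomial coefficients, or knot tables interpolated with monotone
PCHIP).

Shipped defaults and why:

- **Quadratic median equation, "as printed"** (`printed_median_polynomial`):
  `−3.266164164 + 0.368135209·GA − 0.006318278·GA²` over GA 20–41. Evaluated
  over its range this gives ≈ 1.31–2.10 with a single maximum at GA 29.13 —
  the magnitude and shape of a cerebral pulsatility-index median, not of a
  gram-scale fetal weight (term median ≈ 3,200 g). It is therefore shipped
  verbatim under this name, and additionally serves as the default **MCA PI
  median**, whose canonical shape (rise to a peak near 28–30 weeks, then
  fall) it matches.
- **EFW median** (gram scale): a log-quadratic through (20 w, 373.5 g),
  (30 w, 1550 g), (40 w, 3450 g). The 20-week anchor is the mid-trimester
  median consistent with the emulated cohort's 20-week EFW distribution; the
  term anchor is a realistic population median. Strict monotone increase
  over 16–42 weeks is enforced at construction.
- **UA PI median**: a decreasing quadratic through (20, 1.21), (30, 1.00),
  (40, 0.87) — the canonical fall of umbilical impedance with gestation.
- **CPR median**: the ratio of the MCA and UA medians, which makes
  `CPR MoM ≡ MCA MoM / UA MoM` (verified to 1e−9). An independent CPR curve
  can be loaded instead.
- **Centile references**: "local" (log-SD 0.11) and "intergrowth-like"
  (log-SD 0.125) are the same gram-scale median with different spreads. They
  are monotone EFW→centile maps with correct median behaviour — deliberately
  *not* reproductions of the proprietary local standard or the
  Intergrowth-21st skew-normal equations, both of which are pluggable.
- Doppler log-SDs (UA 0.21, MCA 0.22, CPR 0.28) mirror the emulated cohort's
  MoM dispersions.

Gestational age is kept at full precision (weeks + days/7) internally and
rounded to two decimals only for display, avoiding cumulative rounding in
MoM chains.

## Synthetic cohorts

`generate_group_conditional` emulates the reference study population
(defaults: n = 777, 52 events — prevalence fixed by count so the emulation
is exact in sample sizes). Group labels are drawn first; covariates then
come from group-conditional laws parameterised by their natural-scale mean
and SD: log-normal for MoM-type quantities and %ExFW3t (positive, mildly
right-skewed, matching "mean (SD)" table rows exactly in expectation),
normal for maternal height. MCA and UA MoM are drawn jointly through a
Gaussian copula at rank correlation −0.2 (a mild physiological
redistribution assumption — a documented choice, not an observed value);
CPR is **derived** as MCA PI/UA PI at the raw-PI level, so its margins are
emergent. The 20-week EFW MoM is drawn from a single shared law in both
groups, encoding the design's null finding that both groups start from the
same growth potential.

Raw scans are back-solved from the drawn MoM values through the reference
curves (EFW in grams, PIs on their native scale), so re-running the
assessment on the generated file recovers the drawn quantities to 1e−6 —
the whole pipeline, not just summary statistics, runs on synthetic data.
EFW centiles are consequently *derived* from the generated third-trimester
EFW rather than drawn independently: drawing them separately would break
that consistency. Likewise BMI is derived as weight/height² (which
reproduces the intended median ≈ 23) rather than drawn. Nuisance columns
(age, weight, parity, smoking, sex, labor onset, interval to delivery, cord
pH, Apgar, neonatal disposition) are generated to the emulated margins as
static columns so descriptive outputs have the full shape; only the
univariable-significant set feeds the models by default.

`generate_from_logistic` draws covariates from a pooled law and outcomes
from Bernoulli(expit(η)) at user-supplied coefficients; with the shipped
three-term reference risk model it yields ≈ 6% prevalence (≈ 48 events per
777), matching the emulated cohort, and is used for parameter-recovery
simulations.

What the generator does **not** emulate: within-group correlation between
the Doppler and weight-based markers (covariates are conditionally
independent given the outcome group, except MCA↔UA), intervention bias from
unblinded clinicians, the labor-management process, or time-to-delivery
dynamics. A practical consequence: because the real cohort's markers share
a placental-insufficiency pathway and are therefore correlated, the *exact*
AIC ordering of markers is more stable in real data than across synthetic
replicates; on synthetic cohorts the qualitative ordering (cerebral Doppler
above weight-based markers, three-term models on top) holds in roughly
three-quarters of seeds, not near-universally. Passing tests certify the
machinery and the direction of effects, not clinical performance.

## Regression and model comparison

Logistic models are fitted by maximum likelihood (statsmodels' Newton/IRLS
solver, relative tolerance 1e−8, max 100 iterations). Wald SEs come from
the observed information; 95% CIs are `exp(β ± 1.959964·SE)` (Wald, the
standard in clinical logistic reporting; profile-likelihood intervals are
out of scope). Predictors enter untransformed, giving per-unit odds ratios.
Missing data: complete-case per model with the dropped count recorded. No
multiple-testing correction is applied in the univariable screen; the
report footer states this. Perfect or quasi-separation (monotone
likelihood, |β| > 15, or a solver failure) yields a fit flagged
`converged=False`, never a silent result; diverged odds ratios saturate to
infinity rather than raising.

AIC = 2k − 2·logL with k counting the intercept; the identity is asserted
exactly on every fit. Ranking sorts ascending by AIC with ties broken by
higher AUC then fewer parameters, and flags adjacent pairs as
distinguishable iff ΔAIC ≥ 2. Fits on differing n are refused (AIC is not
comparable). The model-level p-value is the likelihood-ratio test against
the intercept-only model.

The eight predefined multivariable models pair a cerebral Doppler anchor
(MCA PI MoM, models 1–4; CPR MoM, models 5–8) with a weight term (local EFW
centile or %ExFW3t), with and without maternal height; the univariable set
comprises the twelve screened parameters.

## ROC analysis

The empirical ROC uses all unique thresholds (no interior points dropped);
AUC is the trapezoidal area and equals the Mann–Whitney U/(n₁n₀) identity
(ties counted half) to 1e−12 — asserted against an independent U-statistic
oracle. The AUC 95% CI uses the DeLong structural-components variance,
implemented here (O(n_pos·n_neg), exact tie handling), clipped to [0, 1];
degenerate AUCs (0 or 1) collapse the interval with a flag. Inverse-risk
markers (MCA, CPR, centiles, %ExFW3t, height) are handled by score
negation (`direction="lower_risk"`).

Detection rate at a fixed FPR uses the conservative step-function
convention — the sensitivity at the largest empirical threshold whose FPR
does not exceed the target — because interpolation conventions differ
between packages; a linearly interpolated variant is available behind
`interpolated_dr` for sensitivity analysis.

Group comparisons: tie-corrected asymptotic Mann–Whitney for continuous
variables (mean (SD); median (IQR) summaries), Pearson chi-square without
continuity correction for categorical ones (with ~50 events and cells ≥ 5
this matches standard practice; Fisher's exact is available behind a flag).

## Pipeline and reproducibility

`run_pipeline` executes assess → describe → univariable screen →
multivariable fits → AIC ranking → ROC export, writing five TSV tables, the
per-model ROC curves, a JSON mirror, and run metadata. Every TSV leads with
a comment line carrying the seed and a SHA-256 hash of the resolved
configuration; metadata contains no timestamps, so identical config + seed
gives a byte-identical bundle (tested). A stage failure aborts with the
stage name and removes partial outputs. The cohort table is never mutated;
assessment columns are a separate table joined on subject_id.

Problem sizes used in the test suite — 200 recovery replicates at n = 777,
1,000 permutation replicates for the type-I check, 1,000 small instances
for the AUC identity, 100 seeds for the ordering replication — keep the
default run to a few minutes on one core while leaving Monte-Carlo error
well inside the asserted bands.

## Known limitations

- The shipped centile references are generic log-normal standards; site
  centiles require loading the site's own curves.
- Wald intervals can undercover with very few events; with ≈ 50 events the
  recovery simulations show 93–97% coverage per coefficient.
- The DR-at-FPR convention of the original analyses is unknowable; the
  step-function choice is conservative and can understate DR relative to
  interpolating implementations.
- The synthetic generator's conditional-independence structure (above)
  limits how sharply replicate-to-replicate model orderings concentrate.
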