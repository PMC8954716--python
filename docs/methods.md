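# Methods

This note records the models, conventions and numerical choices behind
`pps`, in the order the pipeline applies them.

## Synoptic lesion scoring

A scoring scheme is data, not code: a YAML file declaring categories (with
severity caps) and lesions (with a binary or graded scale). The severity of
category *C* for one placenta is

    S_C = min( Σ_{l ∈ C} g_l , cap_C ),

with unobserved lesions contributing 0 and flagged in a per-participant
completeness report. The cumulative severity is Σ_C S_C. Severe maternal
vascular malperfusion (MVM) is `S_MVM ≥ τ` with τ = 2 by default (exposed
as a parameter everywhere it matters).

The shipped default scheme encodes seven categories with caps
14/4/11/5/6/5/6. Which lesion carries which scale is not uniquely
determined by the caps alone; the default assignment makes member
max-grades reach each cap (graded infarction, distal villous hypoplasia,
accelerated villous maturation and syncytial knots plus binary perivillous
fibrin and villous agglutination give 14 for MVM). Two deliberate choices:

* retroplacental hematoma is carried as a binary MVM member, so the MVM
  member grades sum to 15 and the cap of 14 binds at saturation — the cap
  rule, not the lesion list, defines the maximum;
* the chorioamnionitis cap of 11 requires synoptic-form items beyond the
  two inflammatory-response lesions usually tabulated; the scheme adds
  chorionic vasculitis (graded), acute subchorionitis and chorionic-plate
  microabscesses (binary), marked "cap-completing" in the file.

Both are plain YAML edits if a local form differs.

## Lifetime cardiovascular risk

Each of the seven risk factors maps to a stratum in {optimal, not_optimal,
elevated, major} through half-open intervals `[lower, upper)` (numeric
factors) or a direct boolean mapping. The categorical lifetime risk applies
the severity-maximum reading of the protocol list: ≥2 major → 50%; exactly
1 major → 39%; else ≥1 elevated → 39%; else ≥1 not optimal → 27%; else 8%.
The test suite checks this priority order against an independent
"highest-nominated-risk-wins" formulation over all 4⁷ = 16,384 stratum
assignments. Dichotomization is ≥39% → high risk.

The default numeric thresholds are transcribed from the Framingham
lifetime-risk strata (Lloyd-Jones et al. 2006, converted to SI units), with
fasting-glucose strata adapted from ADA fasting-glucose cut-points because
the original stratifies only on diagnosed diabetes; treated hypertension,
diabetes and current smoking map to *major*. These defaults carry external
provenance and are explicitly not the tested contract — the categorization
machinery is; the rules file is user-editable.

Missing measurements follow a configurable policy with default `error`:
silently imputing a clinical screen is unsafe, so imputation
(`impute_optimal`, flagged per participant) and exclusion must be opted
into.

## Association statistics

For a 2×2 exposure-by-outcome table (a, b / c, d):

* odds ratio `OR = ad/bc`; 95% CI on the log scale (Woolf):
  `exp(ln OR ± z_{0.975} √(1/a + 1/b + 1/c + 1/d))`. A zero cell leaves
  the OR undefined by default (flagged); the Haldane–Anscombe +0.5
  adjustment is available by configuration and flagged in the result.
* Pearson chi-square `X² = n(ad − bc)² / (r₁ r₂ c₁ c₂)` with df = 1 and
  **no** continuity correction by default (the Yates correction is a
  config flag for sensitivity analysis). Degenerate margins leave the
  statistic undefined rather than zero.
* Two-group continuous comparisons use Student's t when both samples pass
  Shapiro–Wilk at α = 0.05, otherwise Mann–Whitney U; groups with n < 3 or
  zero pooled variance fall back to Mann–Whitney. The gate is a
  convention, not an inference, and an explicit method override is
  provided; the method actually used is always recorded in the result.
* The two-proportion sample-size operation uses the standard pooled
  normal-approximation formula
  `n = [z_{1−α/2}√(2 p̄ q̄) + z_{power}√(p₁q₁ + p₂q₂)]² / (p₁ − p₂)²`,
  ceiling-rounded, per group. Other conventions (continuity-corrected,
  unpooled) give materially different n; this package documents and tests
  exactly this formula.

Per-lesion frequency tables report unadjusted p-values, matching common
practice for exploratory lesion screens; a Benjamini–Hochberg column can be
appended and is marked as an addition.

## Prediction models

Three pre-registered logistic specifications predict the high-risk screen:
clinical covariates only (maternal age, gestational weight gain, systolic
and diastolic BP at delivery, gestational age at delivery), MVM severity
score only, and combined. "Blood pressure at delivery" is ambiguous in
general use; both pressures enter separately by default, with
systolic-only and MAP switches.

Fits are ordinary maximum likelihood via Newton–Raphson (statsmodels
`Logit`; tolerance 1e-8, ≤100 iterations). A singular Hessian — the
signature of perfect separation — triggers a BFGS refit and a `separated`
flag, as does any |coefficient| > 15 on the log-odds scale; rank-deficient
designs raise an error naming the collinear columns. An intercept-only
specification is allowed and recovers `logit(prevalence)` exactly.

Discrimination is the in-sample (apparent) AUC, computed by the
Mann–Whitney rank identity (ties ½), which the tests pin to brute-force
pair counting and to the trapezoidal area under the empirical ROC at 1e-12.
The AUC CI uses the Hanley–McNeil variance (deterministic; DeLong was the
alternative and can be added without touching the contract). The operating
point maximises Youden's J = se + sp − 1, predicting positive at
score ≥ threshold; ties take the highest (most specific) threshold.
Sensitivity/specificity CIs are Wilson score intervals. No cross-validation
is applied by default: the apparent AUC is the estimand, matching how such
single-cohort screens are usually reported.

## Synthetic cohort generator

The generator's defaults encode the study conditions the pipeline assumes:

* **Lesion presence** is Bernoulli per lesion with prevalence equal to the
  pooled published frequency (count/85); lesions never observed default to
  0. Grades given presence are uniform over the positive grades
  (configurable per lesion). Lesions are independent by default; an
  optional shared latent "placental dysfunction" factor (log-odds sd
  parameter) induces co-occurrence and is documented as extra structure,
  not an estimate.
* **Outcome.** The high-risk screen is Bernoulli with
  `logit(p) = β₀ + ln(OR_target)·1[severe MVM] + Σ β_k z_k`, where z_k are
  standardized delivery covariates with weak default effects (per-SD
  log-odds 0.05–0.15) and β₀ is solved by Brent's method so the mean
  predicted probability among the *non-exposed* equals the baseline rate
  (default 0.51, the published low-exposure row). Default `OR_target` is
  3.1.
* **Back-filled measurements.** Rather than rejection sampling, a stratum
  pattern consistent with the drawn outcome is sampled first (40% of
  low-risk rows all-optimal, 60% ≥1 not-optimal; high-risk rows 35%
  elevated-only / 45% one-major / 20% two-major), then each numeric
  measurement is drawn uniformly inside the intersection of its stratum's
  threshold window with a plausible physiological window, floored at the
  reported precision so rounding can never cross a threshold. Re-screening
  a generated cohort therefore reproduces the intended risk group for
  100% of rows, by construction.
* **Delivery covariates** are clipped normals matched to the published
  combined-cohort means/SDs; gestational age uses a clipped normal
  approximation (mean 35.4, sd 4.3, range 24–42 weeks) of the published
  median/IQR, accepting that the true distribution is left-skewed.

What the generator deliberately does **not** emulate: site effects,
longitudinal structure, lesion–covariate correlation, and the study's
empirical grade distribution. On that last point: only presence
frequencies are published, and uniform positive grades make the severe-MVM
prevalence (~0.8 under the defaults) higher than the study's observed 0.45
— the published cohort evidently carried mostly low grades. The
OR-recovery and coverage properties tested do not depend on the exposure
prevalence; analyses that do should set `grade_distribution` to a
low-grade-heavy alternative. Passing tests on these cohorts show the
*machinery* is correct under known truth, not that any particular clinical
cohort will reproduce the published effect sizes.

A deterministic hand-set 12-participant fixture (`fixture_small`) covers
every lesion category, all four risk categories, an exactly-at-threshold
placenta, a pathology-free placenta and one missing lesion assessment; it
anchors the unit tests and the pipeline round-trip checks.

## Pipeline conventions

* Descriptives use mean ± SD when the column passes the same Shapiro–Wilk
  gate as the group comparisons, else median (IQR) with
  linear-interpolation percentiles (so 1..100 gives 50.5 (25.75, 75.25));
  booleans report n (%). All-missing columns are reported, never dropped.
* Reports carry both unrounded values and display-rounded strings, so
  rounding policy can never hide a discrepancy, plus a provenance block
  (config SHA-256, seed, scheme/rules/package versions). A rerun on the
  same inputs is byte-identical.
* Derived columns present in the input (severity scores, risk groups) are
  recomputed, not trusted.

## Problem sizes and tolerances in the test suite

Simulation-based checks use sizes chosen to make their tolerances sharp on
one CPU: marginal prevalence recovery at n = 100,000 (3 binomial SEs per
lesion), OR recovery at n = 100,000 against the (2.9, 3.3) band around the
generating 3.1, CI coverage over 2,000 replicate tables of 100 exposed /
100 unexposed (accepted band 93–97% for the nominal 95% interval),
coefficient recovery at n = 5,000 within ±0.15, and 100 end-to-end
replicates at n = 400 requiring ≥90% CI coverage of the generating OR. The
whole suite runs in well under a minute.

## Known limitations

* The default per-lesion scale assignment is cap-consistent but not
  guaranteed identical to any particular clinic's synoptic form; the
  scheme file is the source of truth and should be replaced to match local
  practice.
* The default risk thresholds inherit the provenance caveats above;
  anti-hypertensive use is modelled as its own major factor rather than as
  a modifier of the BP strata (the protocol text supports either reading).
* Published AUC-style results from individual-level cohorts cannot be
  reproduced without those data; the package verifies its estimators by
  construction-based simulation instead.
* The Hanley–McNeil AUC variance assumes the binormal-style exponential
  approximation; for heavily tied scores it is conservative.
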