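# Methods

This note documents the statistical models, the synthetic-data design, the
numerical conventions, and the known limitations of `repairscore`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The score model

Case status (non-small cell lung cancer vs healthy control) is modeled by
unconditional logistic regression on the three base-excision-repair enzyme
activities — APE1, OGG1, MPG, measured in PBMC extracts — adjusted for age
(continuous), sex (male indicator), and smoking status (past-vs-never and
current-vs-never indicators). The DNA repair score for subject *i* is the
linear combination of the activities with the fitted enzyme coefficients:

    score_i = w_APE1·APE1_i + w_OGG1·OGG1_i + w_MPG·MPG_i

The adjusting coefficients and the intercept are not part of the score.
The published reference weights are (0.00621, −0.047, −0.0223).

**Orientation.** The raw case-logistic enzyme coefficients point
"case-high". The published score is control-high (control mean 4.00 vs
case mean 2.67; higher score = more repair), so `fit_score_model` returns
the *negated* enzyme coefficients as weights; the raw fit is retained on
the model object. All downstream directions follow from this single
convention: "per 1-SD decrease" effects negate the standardized score
inside the logistic model rather than redefining the score, and ROC
markers built from the score alone are the negated score (higher marker =
more case-like).

**Fitting.** The logistic core is a damped Newton/IRLS iteration on
internally standardized covariates. Convergence requires a relative
log-likelihood change below 1e-10 *and* a gradient infinity norm below
1e-8, after which one extra Newton step is taken (quadratic convergence
then leaves the iterate far below the tolerance, so leave-one-out refits
agree with independent optimizers to ~1e-14). Step halving guarantees a
non-decreasing likelihood up to its floating-point evaluation noise, which
scales with |log-likelihood|; the acceptance threshold is relative for
that reason. Separation is detected two ways: a likelihood approaching
zero (perfect fit) or a diverging standardized coefficient norm; either
raises an error naming the diverging direction. Quasi-separated nuisance
dummies (e.g. never-smoking when a replicate has a single never-smoker
case) converge to large finite coefficients under the gradient criterion
and are reported with their (huge) Wald intervals rather than suppressed —
the same behavior the source cohort showed, with smoking odds ratios near
57.

## Stratification and association

Tertile cutpoints are the 1/3 and 2/3 empirical quantiles of the *control*
scores using linear order-statistic interpolation (numpy's default,
"type 7"); the printed 2-decimal cutpoints cannot distinguish quantile
conventions, so one was fixed and documented. A score exactly at a
cutpoint goes to the *lower* category, matching the printed
"≤ lower cut" / "≥ upper cut" tertile boundaries. The control SD uses the
n−1 denominator.

Two adjusted logistic forms are reported: continuous (score standardized
by the control SD and negated — odds ratio per 1-SD decrease) and tertile
(middle and lowest indicators, highest tertile as referent). Confidence
intervals are Wald throughout, the standard for unconditional logistic
reporting; profile-likelihood intervals are not implemented. COPD is never
an adjuster: it is plausibly a mediator of the repair-cancer association,
and adjusting for mediators is not recommended. An ever-smokers-only
switch reproduces the never-smoker sensitivity analysis.

Adjusted group means use analysis of covariance: OLS of the score on the
grouping factor plus adjusters, summarized as population-averaged
least-squares means (predictions averaged over the whole analysis sample's
covariate distribution with the group label counterfactually set to each
level). The source tables do not state their ANCOVA mean convention;
population averaging was chosen because it makes "no confounding ⇒
adjusted = raw means" an exact identity. Adjuster columns that are
redundant within a subset (e.g. smoking dummies among all-ever-smoker
cases) are dropped automatically; an adjuster that absorbs the grouping
itself raises an error naming the collinear columns. Ordered groupings
(stage, T/N/M) additionally get a linear trend contrast; both the trend
test and all pairwise comparisons are provided because the original
stage-trend testing convention is not stated.

## Optimism correction and ROC inference

Deriving score weights and evaluating their discrimination on the same
subjects overstates performance. `loocv_scores` removes this optimism by
re-deriving the enzyme weights with subject *i* excluded and scoring *i*
from that refit; CV tertile cutpoints and the CV control SD are recomputed
from the CV control scores, following the convention that the tertile
model is then fit once on the CV scores. For covariate-combined markers
the CV marker is the leave-one-out linear predictor — the natural analogue
of the CV score; the source does not state its construction. Refits are
warm-started from the full-cohort fit (verified bit-compatible with cold
literal refit loops); a refit that separates flags the subject and drops
it from CV summaries with a warning.

AUC is the tie-corrected Mann-Whitney concordance (ties count ½). The
empirical ROC curve over all observed thresholds integrates (trapezoid) to
exactly the same number; both are computed on every call and must agree to
1e-12 as an internal consistency check. Sensitivity at specificity *s*
uses the conservative rule: the maximum sensitivity among thresholds whose
specificity is ≥ *s*, with no interpolation.

Bootstrap inference resamples subjects with replacement *stratified by
case status* (preserving the design ratio), refitting the marker-building
procedure inside every replicate; B defaults to 2000. The 95% interval is
BCa: bias correction z₀ from the fraction of replicates below the point
estimate, acceleration from the jackknife skewness of leave-one-subject-out
estimates. A degenerate (zero-variance) bootstrap distribution collapses
the interval to the point estimate. Paired comparisons of two markers use
identical resamples for both; the two-sided p-value doubles the smaller
tail fraction of the bootstrap ΔAUC distribution (capped at 1), with a
normal-approximation p reported alongside. DeLong's analytic comparison is
deliberately not implemented: the bootstrap route is the one being
mirrored.

## Absolute-risk updating

The baseline absolute risk (for instance a Liverpool Lung Project 5-year
risk) is an *input*; the LLP model is not reimplemented. For a score
region defined by control-distribution percentiles (e.g. "≤ 5th control
percentile"), the likelihood ratio is

    LR = P(score ∈ region | case) / P(score ∈ region | control)

with probabilities from the binormal model (defaults: control
N(4.00, 0.98²), case N(2.67, 1.06²)) or from empirical score vectors
(≥ 20 per group). The update is exact Bayes: posterior odds = prior odds ×
LR. This is the *marginal* LR — it conditions on nothing but case status.
The original study's exact combination rule lives in an unavailable
supplement and its printed worked examples (1.6% → 6.9%, 4.5% → 1.1%)
are not reproducible from the main text: the marginal LR gives
1.6% → 11.4%. Those printed numbers are therefore treated as documentation
anchors, not targets. A covariate-conditional variant is available by
passing residual scores (score minus a covariate-model prediction) in
empirical mode.

The case-group SD 1.06 is itself derived, not printed: from the case 95%
CI half-width (0.17) at n = 149, SD = 0.17·√149/1.96 ≈ 1.06.

## Expression association and enrichment

Counts are normalized by median-of-ratios size factors (computed over
genes expressed in every sample, rescaled to geometric mean 1). Per gene,
within one group at a time (cases or controls), ordinary least squares
regresses log2(count/size_factor + 0.5) on the score plus sex, age,
smoking, and batch; the Wald t on the score slope gives BH q-values and
the signed-t rank metric. This OLS-on-log-normalized-counts statistic
*replaces* a negative-binomial Wald test deliberately: the downstream use
is only a gene ranking, and the substitution is transparent and testable.
Genes with mean normalized count below 5 are excluded before testing (a
documented stand-in for unspecified upstream data cleaning). Genes exactly
constant across samples get slope, SE, and t of exactly 0; near-noiseless
fits are capped at |t| = 1e6.

Preranked enrichment follows the weighted Kolmogorov-Smirnov running sum
with weight exponent 1: walking the list ranked by decreasing metric
(ties broken by gene id for determinism), a member gene adds
|r|/Σ_set|r| and a non-member subtracts 1/(N−k); the enrichment score ES
is the signed extremum of the walk. When the maximum and minimum have
exactly equal magnitude the ES takes the extremum reached first — a pure
tie-break on a measure-zero event. The null permutes gene labels
(equivalently, draws random same-size sets; draws are shared across sets
of equal size). NES divides ES by the mean |null ES| of matching sign; p
is the matching-sign null tail fraction; FDR q follows the pooled-null
convention (fraction of pooled null NES at least as extreme, over the
fraction of observed NES at least as extreme, per sign, capped at 1).
Defaults mirror common enrichment practice: min set size 15, max 500,
1000 permutations. Pathway names are curated into immune / cell-cycle /
other groups by case-insensitive keyword matching with immune taking
precedence on double matches; the keyword lists are configurable defaults,
since the original curation list is unavailable.

`subsample_robustness` reruns association + enrichment on random sample
subsets (without replacement, stratified by batch when present) and counts
significant sets per pathway group; the permutation seed is held fixed
across repeats so a fraction of 1.0 reproduces the full-data result
identically.

## Synthetic-data design

**Cohort.** The generator is score-first: a latent score is drawn from the
group normal (controls N(4.00, 0.98²); cases N(2.67, 1.06²)), OGG1 and
MPG from truncated-positive normals, and APE1 is solved from the score
identity — so recomputing the score from the emitted activities reproduces
the latent draw exactly, and only the score distribution (the quantity the
study calibrates) is pinned to published values. Individual
enzyme-activity scales are not published; the defaults OGG1 ~ N(7.0, 1.5),
MPG ~ N(15.0, 3.0) are conventions, and joint draws implying a
non-positive APE1 (probability ~8e-4 for a case) are rejection-resampled.
Covariates follow the published marginals: age N(59.7, 10.0²) controls /
N(68.6, 9.6²) cases (floored at 18), 55.2% / 62.0% male. Smoking is
assigned by permuting the exact printed analyzed-cohort counts
(45/49/46 never/past/current controls; 1/87/61 cases) whenever the group
size matches them — guaranteeing the single never-smoker case appears in
every replicate, as in the source cohort — and multinomially otherwise.
Score, age, sex, and smoking are conditionally independent given case
status by default; a `score_age_corr` knob exists for sensitivity
experiments. Pack-years, COPD, stage, and TNM fields are generated with
plausible marginals for interface completeness; no analysis depends on
their exact values.

**Counts.** Negative binomial with gene-wise constant dispersion (default
0.2) and log2 mean = baseline_g + β·score·(group indicator) + batch offset
+ log2(library size). The immune gene block uses β = −0.5 per score unit
*in case samples only* (expression rises as repair falls, only in
patients); the cell-cycle block uses β = −0.25 in both groups. Library
sizes are lognormal (median 1e6), batch offsets normal with SD 0.1. A
dispersion of exactly 0 is a documented degenerate mode: counts are the
rounded means with no sampling, for exactness tests. Fixture gene sets are
pairwise disjoint by construction, drawn from the matching gene block,
with keyword-bearing names.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: gene-gene correlation beyond the shared score
effect, assay measurement error in the activities, joint score-covariate
dependence (see below), realistic pathway overlap structure, or
library-preparation artifacts beyond a scalar batch offset.

## Problem sizes and observed behavior of the calibrated simulation

The acceptance computations use the study's own dimensions: cohorts of
140 controls + 149 cases; 100 simulation seeds for apparent-AUC summaries
and 50 for the leave-one-out one; coefficient-recovery checks at n = 4000
over 100 replicates; BCa coverage at n = 150+150, B = 500, 200 outer
replicates; enrichment asymmetry at 200 genes × 200 samples with 500
permutations over 20 seeds. These sizes keep every check cheap while
leaving Monte-Carlo error well below the tolerances involved.

One calibration tension is worth recording. Under conditional independence
of score and covariates given case status, the simulated mean *apparent*
AUC of the combined score + age + sex + smoking predictor sits near 0.911
(the score-only and cross-validated values land near 0.820 and 0.894) —
slightly above the real-cohort combined value of 0.89. In the real cohort
the score declines with age among controls, making score and age partially
redundant; the independence design removes that redundancy and so
slightly over-separates. Calibrating a score-age dependence from the
printed age-group means would close the gap but would leave the stated
simulation design; the independence default is kept and the discrepancy
documented instead.

A related, intentionally accepted artifact: with a *bilateral* cell-cycle
signal active, 30 of 200 genes occupy the bottom of the control ranking,
displacing null genes upward and inflating immune-set false positives in
controls — the classic relative-rank limitation of gene-permutation
enrichment with few genes. The case/control asymmetry experiment therefore
plants only the case-specific immune signal, leaving the control ranking
genuinely null.

## Degenerate inputs and numerical conventions (summary)

- Quantiles: numpy type 7 (linear interpolation); SDs: n−1.
- Cutpoint ties: lower category. AUC ties: ½ credit.
- Logistic: standardized-space Newton, tol_ll 1e-10 relative, tol_grad
  1e-8, max 100 iterations, separation via likelihood → 0 or coefficient
  norm > 1e4.
- BCa with all bootstrap replicates equal: collapsed interval.
- Bootstrap replicates with one outcome class: redrawn, capped at 10·B.
- Constant genes: exact zero statistics; |t| capped at 1e6.
- Empty/undersized/oversized or non-overlapping gene sets: skipped with a
  recorded reason, never silently dropped.
- All randomness flows through explicit integer seeds (numpy Generator);
  pipelines echo seeds and input hashes into JSON manifests.

## Known limitations

- The marginal likelihood ratio for risk updating ignores the correlation
  structure between the score and the covariates already inside the
  baseline risk model; the covariate-conditional variant mitigates but
  does not resolve this without the original combination rule.
- Wald intervals degrade for quasi-separated cells (they are reported as
  such rather than replaced by profile or exact intervals).
- The per-gene OLS ranking is not a shrinkage estimator; at very small
  sample sizes its tail ordering is noisier than a moderated statistic.
- The generator's conditional-independence default slightly overstates the
  combined model's discrimination relative to the source cohort (above).
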