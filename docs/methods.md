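# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Normalization

NanoString-style counts are assumed background-corrected; cartridge-level
artifacts (positive/negative controls, binding density, lane effects) are
out of scope and the interchange format is a plain TSV/CSV matrix, not the
platform's binary RCC files. Housekeeping scaling equalizes the geometric
mean of the control genes (GAPDH, ACTB, TUBB, treated jointly) across
samples, with the cross-sample arithmetic mean of those geometric means as
the reference; a frozen numeric reference can be supplied instead (the
`HousekeepingNormalizer(reference=...)` parameter) so new cohorts can be
scaled against an earlier one. A housekeeping count of zero makes the
geometric mean undefined and is an error naming the sample, not a silent
imputation. The log2 transform uses an offset of +1 count, keeping zeros
finite while leaving large counts essentially unchanged.

Scaling is idempotent and commutes with sample permutation; both are
enforced by tests at 1e-9.

## Differential expression

Tumour-vs-normal contrasts use a moderated t-statistic on normalized log2
values. Per transcript, the pooled two-group variance s_g² (d_g = n1+n2−2
degrees of freedom) is shrunk toward a prior s0² with prior degrees of
freedom d0, and the statistic is referred to t on d0 + d_g df. The prior is
estimated by moment-matching log s_g² to a scaled F distribution: with
e_g = log s_g² − ψ(d_g/2) + log(d_g/2), the excess of the sample variance
of e over ψ′(d_g/2) determines d0 through a trigamma inversion (Newton
iteration), and the mean of e determines s0². When the log variances show
no excess dispersion, d0 = ∞ and all transcripts share s0² (normal
reference distribution). The implementation agrees with an independent
empirical-Bayes reference implementation to ~1e-8 on random data (tested).
A Welch t-test is available as a shrinkage-free fallback; a zero-variance
transcript with a nonzero shift reports an infinite statistic with p = 0
and a warning rather than NaN.

Fold change is tumour minus normal on the log2 scale. FDR control is
Benjamini–Hochberg step-up at α = 0.05 (statsmodels backend, hand-checked).
Each transcript (isoform) is an independent row; multi-factor designs and
count-level precision weighting are out of scope.

## Unsupervised views

Classical (Torgerson) scaling of the Euclidean distance matrix between
sample profiles gives the low-dimensional map (principal-coordinates
backend from scikit-bio); coordinates reproduce the input distances up to
spectral truncation, which the tests check at full rank. Hierarchical
clustering uses average linkage on the same distances (scipy), exported in
a Newick-style nested format. Subgroup count selection fits Gaussian
mixtures with diagonal covariances for k ∈ {1, 2, 3} — diagonal because the
input is a 2-D ordination where axis scales differ and the sample size is
small — using k-means++ seeding, 10 restarts, tolerance 1e-8, at most 500
EM iterations and a fixed seed; the winner minimizes BIC.

## Survival machinery

Time is months throughout; "5-year" means evaluation of the
right-continuous product-limit step function at exactly 60 months. The
Kaplan–Meier estimator and the k-group log-rank statistic (observed minus
expected with hypergeometric variance at each distinct event time,
chi-square on k−1 df) are computed directly: the log-rank statistic is the
inner loop of the cut-point scan and needs a form vectorizable over
candidate thresholds. Both are cross-checked against lifelines in the test
suite. Cox regression delegates to lifelines (partial likelihood, Efron
ties — the convention pinned here since the tie treatment was otherwise
open), as do the scaled-Schoenfeld proportional-hazards test (KM time
transform, the cox.zph convention) and, via statsmodels, the variance
inflation factor.

## Optimal cut-point and its known bias

Candidate thresholds are the midpoints between consecutive distinct
expression values whose split leaves each arm at least `min_arm_fraction`
(default 0.10) of the cohort — exhaustive over distinct dichotomizations
and invariant to monotone candidate re-parameterization. The chosen
threshold minimizes the two-group log-rank p; ties break to the smaller
threshold. The high-risk side is the arm with the larger event rate per
unit follow-up. The chosen p equals a brute-force per-candidate
recomputation with an independent log-rank implementation (tested).

Selecting the minimizer of a p-value is anti-conservative: with expression
independent of survival (n = 100, 20% drop-out), the minimal p is below
0.05 in 45.5% of 200 fixed-seed null cohorts. That rate is pinned as a
regression value in the tests; no multiplicity correction is applied,
matching how such cut-off searches are commonly used, and reported
cut-point p-values should be read accordingly.

Sampling precision of the procedure itself: at n = 200 with a hazard ratio
of 3 across the true threshold and complete follow-up, the chosen
threshold's quantile has standard deviation ≈ 0.046 around the truth, so
recovery is assessed within ±10 percentile points (achieved in ≈ 96% of
seeds); a ±5-point band is tighter than the procedure's intrinsic
variability (≈ 74% even with every death observed) and is therefore not a
meaningful acceptance band for any implementation of this search.

## The three-gene score

Defaults encode the risk rules: ADH1B (NM_001286650) ≥ 4.39 high risk;
BST2 < 10.34 high risk; FER1L4 < 4.73 high risk (normalized log2 units;
boundary values fall on the side written in each inequality). The score is
min(k, 2) over the high-risk count k, and is monotone: raising ADH1B or
lowering BST2/FER1L4 never lowers k. Note the directions: for BST2 and
FER1L4 *low* expression is the adverse state, consistent with their
univariate association of lower expression with shorter OS; loose verbal
shorthand like "expressed at high levels" for the adverse state conflicts
with these inequalities, and the inequalities win here. Both thresholds and
directions are configurable (`ScoreConfig`).

## Synthetic cohorts

The generator emulates the study design: 66 tumours vs 10 nontumoral
samples, 28 target transcripts plus the three controls. Counts are
log-normal (rounded to integers) around per-transcript baseline log2
means — the simplest count model consistent with an analysis conducted
entirely on the log2 scale; a negative-binomial option exists for
overdispersion at the count level. A per-sample library-size offset
(log2 sd 0.25) is added to every gene and is exactly what housekeeping
scaling removes. Housekeeping noise is small (log2 sd 0.15) by the
stability assumption that justifies using them as controls.

Score-gene expression in tumours is drawn on a definite side of each
threshold with a margin of at least 0.5 log2 units (|N(1.2, 0.5)| clipped),
so every patient's true high-risk state is recorded and consistent with
the normalized expression (tested exactly). Per-gene high-risk prevalence
defaults to 0.415, making the expected score-group split ≈ 0.20 / 0.43 /
0.37, i.e. close to 11/23/21 out of 55. Other transcripts carry their
configured tumour shifts (defaults are the panel's reported fold changes;
remaining panel members are nulls, and the panel itself is synthetic —
real transcripts could not be enumerated beyond the reported ones).

Overall survival is exponential per risk group with rates from
`calibrate_hazards`: λ = −ln(S₅ᵧᵣ)/60 for targets (0.91, 0.83, 0.52). A
single per-gene multiplicative hazard multiplier cannot reproduce all
three targets (the implied rate ratios 1.98 and 3.51 are unequal), so
group-level hazards are the default and per-gene multipliers are an
explicit alternative configuration. Disease-free survival is min(relapse,
death) with relapse hazard a configurable multiple (default 1.5) of the
death hazard. Censoring combines an administrative follow-up limit at 79
months with uniform-on-(0, 79) early drop-out for a Bernoulli(0.20)
subset — Kaplan–Meier estimates are unbiased under either component.
Clinical covariates are drawn from the study's marginal distributions and
are independent of expression and survival; they exercise table plumbing
and the association/Cox interfaces but carry no signal.

What passing tests therefore show: the pipeline recovers known structure
(fold-change signs, class separation, score-group survival targets,
thresholds under a step hazard) under independence across transcripts,
log-normal noise, exponential hazards and non-informative censoring. What
they do not show: robustness to correlated transcripts, count-level
overdispersion beyond log-normal, informative censoring, or covariate
confounding — all absent from the generator by design (transcript
correlation is configurable only via a custom panel; the default is
independence).

## Association tables

Expression is dichotomized strictly-below vs at-or-above a stated cut-off
and cross-tabulated against categorical clinical variables. The test is
Pearson's chi-square *without* continuity correction — the choice validated
by recomputing the published 2×2 tables, which reproduce their printed
p-values (0.03, 0.003, 0.01, 0.02, 0.03, 0.05) only without correction;
Yates correction remains available as an option. Cells with expected
counts below 5 are flagged, not auto-switched to an exact test. A few
published table cells do not reproduce from their printed counts under any
correction setting (computed 0.05 vs printed 0.02; 0.065 vs 0.02; 0.027 vs
0.05); the pipeline always reports its own computed values.

## Pipeline and determinism

`run_pipeline` is a pure function of (inputs, config, seed): stages write
TSV/JSON artifacts plus a manifest with each file's SHA-256 and the
effective config; identical inputs and seed give identical hashes (elapsed
times are logged, never written into the manifest). Stage failures
propagate with the stage name; earlier artifacts are preserved.

## Problem sizes used in the test suite

Simulation-based checks use cohorts of the study's size (66 + 10) or
smaller, 50–200 seeds per property, 1000 label permutations for the
log-rank type-I check, and n = 10⁴ only for closed-form Monte-Carlo
verification — sizes at which each property's Monte-Carlo error is well
inside the asserted band while the whole suite runs in well under a
minute.

## Known limitations

- The minimal-p cut-point is reported uncorrected (by design, documented
  above); confidence in a discovered threshold requires external
  validation.
- The moderated-t assumes exchangeable variances across transcripts; with
  only 28 panel members the prior df estimate is itself noisy.
- Group-level hazards make score-group survival exactly exponential; real
  cohorts mix histories within a score group.
- No GEO fetcher: external validation series must be supplied as
  pre-downloaded matrices in the package's matrix dialect.
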