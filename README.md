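# crcpanel

Analysis pipeline for a 28-gene NanoString nCounter expression panel in
sporadic colorectal cancer (sCRC): housekeeping normalization,
tumour-vs-normal differential expression, survival-based optimal cut-point
discovery, and a three-gene prognostic risk score that stratifies patients
into three overall-survival (OS) risk groups. A synthetic-cohort generator
with the same statistical structure makes every stage testable without
patient-level data.

## Who this is for

Translational researchers working with targeted expression panels (counts
for a few dozen transcripts plus housekeeping controls) and right-censored
survival endpoints, who want the full path from raw counts to a count-based
multigene risk score as reusable, tested code rather than a chain of
one-off scripts and web tools.

## The model

**Normalization.** Counts are scaled per sample so housekeeping geometric
means equalize: for sample *j* with housekeeping genes *H* (GAPDH, ACTB,
TUBB),

```
factor_j = mean_k( geomean_{g in H} c_gk ) / geomean_{g in H} c_gj
```

then values are log2(count + 1).

**Differential expression.** Per transcript, an empirical-Bayes moderated
t-statistic on the log2 scale: pooled variances s_g² (d_g df) shrink toward
a prior s0² with d0 df estimated by moment-matching the log variances to a
scaled F distribution; t uses posterior variance
(d0·s0² + d_g·s_g²)/(d0 + d_g) on d0 + d_g df. Benjamini–Hochberg controls
the FDR at α = 0.05.

**Optimal cut-point.** For each gene, every midpoint between consecutive
distinct expression values that leaves ≥ 10% of patients in each arm is
tested with the two-group log-rank statistic; the threshold with minimal p
is selected. This minimal-p selection is anti-conservative under the null
(measured: min-p < 0.05 in ≈ 46% of null cohorts); the package documents
rather than hides this — see `docs/methods.md`.

**Risk score.** With thresholds in normalized log2 units, a patient's
high-risk count is

```
k = [ADH1B ≥ 4.39] + [BST2 < 10.34] + [FER1L4 < 4.73],   score = min(k, 2)
```

giving low (0), intermediate (1) and high (2) risk groups, compared by
Kaplan–Meier curves, survival at 60 months ("5-year OS") and the k-group
log-rank test. Cox proportional-hazards fits (Efron ties, via lifelines)
with VIF and Schoenfeld diagnostics cover the multivariate analysis.

## Worked example

```python
import numpy as np
from crcpanel import (SimulationConfig, generate_cohort, preprocess,
                      differential_expression, apply_score,
                      stratify_and_summarize, DEFAULT_SCORE_CONFIG)
from crcpanel.matrix import align_samples, endpoints_from_clinical

cohort = generate_cohort(SimulationConfig(seed=1))   # 66 tumours, 10 normals
norm = preprocess(cohort.expression)                 # normalize + log2
de = differential_expression(norm, alpha=0.05)
print(f"{int(de.significant.sum())} of {len(de)} transcripts significant")

tumour, clinical = align_samples(norm, cohort.clinical)
time, event = endpoints_from_clinical(clinical, "OS")
expr3 = np.column_stack([tumour.gene_row(t)
                         for t in DEFAULT_SCORE_CONFIG.transcript_ids])
scores = apply_score(expr3, patient_ids=tumour.samples)
summary = stratify_and_summarize(scores["score"].to_numpy(), time, event)
for g in sorted(summary.curves):
    print(f"score {g}: n={summary.group_sizes[g]:2d}, "
          f"5-year OS = {100 * summary.five_year_os[g]:.0f}%")
print(f"three-group log-rank p = {summary.logrank.p:.4f}")
```

Output:

```
13 of 28 transcripts significant
score 0: n=14, 5-year OS = 85%
score 1: n=26, 5-year OS = 72%
score 2: n=26, 5-year OS = 78%
three-group log-rank p = 0.8234
```

The differential-expression stage recovers the configured fold changes
(e.g. SPP1 +5.95, ADH1B −5.34 on this seed). The survival stratification of
a *single* 66-patient cohort is noisy — group KM estimates at 60 months
carry wide confidence bands at n ≈ 14–26 per group — which is why recovery
of the generator's 5-year targets (91% / 83% / 52%) is assessed as a median
over 100 cohorts (see below), where the estimates centre on the targets.

A CLI mirrors the stages:

```
crcpanel simulate --seed 1 --out-prefix cohort
crcpanel run --expression cohort_expression.tsv --clinical cohort_clinical.csv \
             --out-dir out --seed 1
```

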