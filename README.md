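# metaepi

Meta-epidemiology of design bias in clinical prediction rule validation
studies.

A clinical prediction rule (CPR) combines several findings from history,
examination or simple tests into an outcome probability. Before a CPR is
used on patients it should be validated in new populations — but validation
studies themselves can be biased: case-control sampling, differential
verification, small samples, non-consecutive enrolment and other design
shortcuts can inflate the apparent performance. `metaepi` quantifies that
inflation across a collection of meta-analyses of validation studies.

## The model

Each validation study yields a diagnostic 2×2 table and hence a diagnostic
odds ratio, DOR = (TP·TN)/(FP·FN). Writing

- *D* = logit(TPR) − logit(FPR) = ln DOR,
- *S* = logit(TPR) + logit(FPR) (a proxy for the positivity threshold),

the pipeline runs in two stages:

1. **Within each meta-analysis** (one rule at one threshold), a
   Moses–Littenberg meta-regression

   *D*ᵢ = a + b·*S*ᵢ + Σₖ γₖ·*Z*ᵢₖ + εᵢ,

   weighted by 1/(var(ln DOR) + τ²) with the Woolf variance
   1/TP + 1/FP + 1/FN + 1/TN and a moment estimate of the residual
   between-study variance τ². Each binary design covariate *Z*ₖ (e.g.
   "case-control design" vs "cohort or unclear") gets a coefficient
   γₖ = ln RDOR, the log relative diagnostic odds ratio: exp(γₖ) is the
   factor by which the flaw multiplies the DOR, adjusted for threshold.

2. **Across meta-analyses**, the γₖ estimates are pooled by
   DerSimonian–Laird random effects (moment τ², inverse-variance weights
   1/(se² + τ²), z-based CIs) into a **summary RDOR** per design
   characteristic, with Q, τ² and I² heterogeneity statistics and
   exclusion / leave-one-out / fixed-effect sensitivity variants.

A summary RDOR above 1 means studies with the design flaw report inflated
performance. The package also provides per-study accuracy statistics,
Fagan-style post-test probabilities, Cohen's kappa for extraction
agreement, and a synthetic-data generator that draws datasets from exactly
this model so the whole pipeline is testable by parameter recovery.

## Worked example

The analysis scripts under `analysis/` run the full pipeline on synthetic
data. `python analysis/05_worked_clinical_example.py` prints:

```
reported sens = spec = 90%  ->  DOR = 81
combined overestimation factor: 4.2
bias-adjusted DOR = 19.4  ->  sens = spec = 81%
post-test probability at 10% pre-test risk:
  biased accuracy:   50% (LR+ = 9.0)
  adjusted accuracy: 33% (LR+ = 4.4)
```

A rule validated at 90%/90% (DOR 81) in a study with both an inadequate
sample size (summary RDOR 1.9) and a case-control design (summary RDOR 2.2)
is expected to be overestimated 1.9 × 2.2 ≈ 4.2-fold; the debiased DOR of
about 19 corresponds to sensitivity = specificity ≈ 81%, and for a patient
with a 10% pre-test probability the rule-positive post-test probability
drops from 50% to about a third.

Running the simulated two-stage analysis
(`analysis/01…` → `analysis/04…`) generates 30 meta-analyses with
case-control, differential-verification and sample-size effects injected at
2.2 / 2.0 / 1.9, fits them, and recovers (100 replicates):

```
covariate                     true   mean    sd bias(log) coverage
inadequate_sample_size        1.90  1.876  0.25    -0.021     0.90
case_control_design           2.20  2.193  0.31    -0.013     0.94
differential_verification     2.00  1.997  0.41    -0.022     0.90
```

## Command line

```sh
metaepi simulate --seed 17 --out synth.csv          # synthetic dataset
metaepi run --input synth.csv --out results/run     # full pipeline
metaepi stage1 --input synth.csv --out fits.tsv     # meta-regressions only
metaepi stage2 --fits fits.tsv --out summary.tsv    # DL pooling only
metaepi fagan --pretest 0.10 --sens 0.90 --spec 0.90
metaepi kappa --ratings ratings.csv
```

Input CSV columns: `meta_id, study_id, tp, fp, fn, tn` plus optional design
columns (`sample_size, patient_selection, spectrum, validation_type,
assessment, verification, data_collection`); level labels are normalized
case-insensitively and unknown/missing levels become `unclear`. XLSX input
is supported through a user-supplied column mapping.

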