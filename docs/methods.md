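# Methods

## Estimand and data model

The unit of analysis is a *validation study* of a clinical prediction rule,
summarised by its diagnostic 2×2 table and a profile of seven design
characteristics (sample size, patient selection, disease spectrum,
validation type, assessment blinding, verification, data collection), each
taking a small set of nominal levels with `unclear` always legal. Studies
are clustered into meta-analyses (one rule at one positivity threshold);
meta-analyses with fewer than four studies are flagged and excluded from
fitting.

The estimand for each design characteristic is the **relative diagnostic
odds ratio (RDOR)**: the ratio of the DOR of studies carrying the flaw to
the DOR of studies without it, adjusted for threshold and for the other
flaws. The RDOR is a multiplicative effect on the DOR, i.e. additive on
ln DOR — this log-additive structure is what the two-stage estimator and
the synthetic-data generator both assume.

## Stage 1 — Moses–Littenberg meta-regression

Per study, on continuity-corrected counts (0.5 added to *all four* cells
iff any cell is zero; counts untouched otherwise):

- D = logit(sens) − logit(1 − spec) = ln DOR,
- S = logit(sens) + logit(1 − spec),
- var(ln DOR) = 1/tp + 1/fp + 1/fn + 1/tn (Woolf).

Within each meta-analysis, D is regressed on an intercept, S and the 0/1
design covariates by weighted least squares. Weighting modes:

- `fixed_effect`: weights 1/varᵢ; covariance (XᵀWX)⁻¹.
- `random_effects` (default): from the fixed-effect fit's weighted residual
  sum of squares Q_res, the moment estimator
  τ²_reg = max(0, (Q_res − df) / tr P), P = W − WX(XᵀWX)⁻¹XᵀW,
  then a refit with weights 1/(varᵢ + τ²_reg). This is the
  DerSimonian–Laird moment estimator generalised to a regression and is
  numerically identical to `metafor::rma(method = "DL")` with moderators
  (asserted in the test suite).
- `unweighted`: OLS with the usual σ̂²(XᵀX)⁻¹ covariance.

Covariates constant within a meta-analysis are dropped before fitting (they
are collinear with the intercept and the meta-analysis carries no
information about them); the drop is recorded so stage 2 knows each
covariate's effective evidence base. A rank-deficient design or residual
df < 1 causes the meta-analysis to be skipped with a logged reason rather
than regularised.

## Covariate coding

The default multivariable scheme uses six collapsed binary contrasts
(exposed = 1): inadequate vs adequate sample size (adequate = at least 100
patients with and 100 without the outcome); nonconsecutive vs
consecutive/unclear selection; case-control vs cohort/unclear spectrum;
narrow vs broad/unclear validation; differential vs
complete/partial/unclear verification; unclear vs prospective/retrospective
data collection. Blinding is excluded by default because it is too rarely
reported to be estimable in most meta-analyses, but can be re-included
(`include_assessment`).

Two genuinely open coding choices are configuration switches with
documented defaults:

- **Internal validation** is grouped with the exposed (narrow) side by
  default (`internal_validation_policy = narrow`): an internal validation
  is at most as stringent as a narrow one, so grouping it with the
  reference would dilute the narrow-validation contrast. `reference` and
  `exclude` are available.
- **Univariable mode** keeps the original levels, one indicator per
  non-reference level (references: adequate, consecutive, cohort, broad,
  blind, complete, prospective), each indicator fitted in its own
  regression with the remaining levels excluded, so every univariable
  contrast compares exactly two groups.

## Stage 2 — DerSimonian–Laird pooling

Per covariate, the per-meta-analysis coefficients (γⱼ, seⱼ) are pooled with
the standard DL moment method (Q, τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)),
weights 1/(seⱼ² + τ²), I² = max(0, 100(Q − (k−1))/Q)); the summary RDOR is
exp(θ̂) with z-based CIs (95% default, configurable). Knapp–Hartung
adjustment is deliberately not used, matching the Stata `metaan`
DL option this pipeline mirrors. Sensitivity variants re-pool after
excluding named meta-analyses (outlier diagnostics), leave-one-out, and
under the fixed-effect model. Reports round RDOR and CI to one decimal and
I² to one decimal.

## Synthetic data generator

The generator draws from exactly the model the estimator assumes, so
parameter recovery isolates pipeline correctness:

| parameter | default | meaning |
|---|---|---|
| `n_meta` | 30 | meta-analyses per dataset |
| `studies_per_meta` | 4–20 | uniform; two thirds of real meta-analyses pooled ≤ 10 studies |
| `baseline_ln_dor_mean` | 3.0 | typical DOR ≈ 20 (sens = spec ≈ 82%) |
| `baseline_ln_dor_sd` | 0.8 | between-meta-analysis spread of baseline accuracy |
| `tau2_study` | 0.25 | within-meta between-study variance of ln DOR |
| `s_spread` | 0.8 | SD of the threshold proxy S |
| `flaw_prevalence` | cc 0.192, diff 0.10, inad-n 0.50, noncons 0.15, narrow 0.30, unclear-dc 0.20 | Bernoulli probability of each flaw; case-control matches the observed 19.2% rate, the rest emulate the reported mix |
| `prevalence_range` | 0.2–0.6 | per-study disease prevalence (uniform) |
| `n_range` | 40–2000 | per-study total size (log-uniform) |

Per study, D = β_m + Σ γₖZₖ + u with u ~ N(0, τ²_study), S ~ N(0,
s_spread²); logit(TPR) = (S+D)/2 and logit(FPR) = (S−D)/2, so exp(D) is the
study's true DOR by construction; TP and FP are binomial draws. The
sample-size flaw is realised consistently in the counts: an "inadequate"
study draws a total below 200 (one arm necessarily < 100), an "adequate"
one draws both arms ≥ 100 (arm counts are clipped into range rather than
redrawn, so both arms are always ≥ 1 and the realised class always matches
the drawn flaw). All randomness flows from one seeded
`numpy.random.Generator`; replicate r of a recovery run uses seed + r.

What the generator does **not** emulate: real thresholds (threshold
variation enters directly through S, the quantity the Moses model adjusts
for, rather than through explicit cutoffs on a marker); correlation between
flaws within a study or clustering of flaws within meta-analyses;
reporting-quality characteristics; any specific clinical domain. Passing
recovery tests therefore demonstrate that the estimator inverts its own
assumed data-generating process, not that the model is correct for any
particular real dataset.

## Numerical choices and degenerate inputs

- All computation is on the natural-log scale; exponentiation happens at
  reporting time only.
- Continuity correction (add 0.5 to all cells iff any is zero) follows the
  Haldane–Anscombe convention standard in DOR meta-analysis; an all-zero
  table is an error.
- τ² and I² are truncated at zero; a non-positive trace correction in the
  stage-1 moment step yields τ²_reg = 0.
- k = 1 pooling returns the single estimate with Q = 0 and a logged caveat;
  pooling nothing is an explicit "not estimable" error, as is requesting an
  RDOR for a dropped covariate.
- Level labels are normalized case-insensitively with a fixed alias table;
  unknown labels map to `unclear` with a warning. An explicitly supplied
  sample-size class wins over the count-derived one (manual extraction is
  authoritative), with a warning when they disagree.
- Ties/ordering: grouping preserves file order; fits and reports are
  deterministic given input order and seed (re-running a pipeline from its
  echoed config is byte-identical, asserted in tests).

## Known limitations

- **Interval calibration.** Stage-1 SEs come from the weighted
  normal-equations covariance and both stages use z (not t or
  Knapp–Hartung) intervals. With 4–20 studies per meta-analysis and up to
  eight parameters, these SEs underestimate the true sampling variability
  of the coefficients, and z-based DL intervals themselves undercover
  slightly at moderate k. The recovery harness measures the consequence
  directly: pooled point estimates are essentially unbiased, while
  empirical 95% CI coverage under the null sits a point or two below
  nominal. Users wanting conservative intervals should prefer the
  fixed-effect sensitivity variant only for homogeneous inputs and treat
  borderline CIs with caution.
- The Moses–Littenberg model is a study-level approximation; no bivariate
  or hierarchical SROC model is provided, and no permutation inference.
- The two-stage approach discards meta-analyses where the multivariable
  design is not estimable (few, homogeneous studies); covariates rare
  within meta-analyses (e.g. differential verification) consequently pool
  over fewer clusters and carry wider intervals.
- Spreadsheet layouts vary; XLSX reading requires a user-supplied column
  mapping rather than guessing.
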