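# Methods

## The product-correlation decomposition

For genes *a*, *b* measured over *n* samples of one condition, let *z*ₐ,
*z*ᵦ be the expression vectors centered and scaled to sample SD 1
(denominator *n* − 1). The per-sample products *p*ᵢ = *z*ₐᵢ·*z*ᵦᵢ satisfy
Σ *p*ᵢ/(*n* − 1) = Pearson *r* exactly, so the products are a lossless
per-sample decomposition of the correlation. All differential-coexpression
inference in this package operates on these products.

Two test forms are provided, matching two study designs:

- **Paired form** (`cilp_test_paired`, `cilp_screen_paired`): with matched
  tumor/normal samples per subject, per-subject product differences
  (tumor − normal) are tested with a two-sided paired *t*-test. This is the
  regression model degenerated to its paired special case, and is the form
  used for the main DCL screen.
- **Regression form** (`cilp_test_regression`, `cilp_screen_regression`):
  products from the stacked samples of both conditions are regressed by OLS
  on an intercept, the condition indicator, and the two genes' z-scored
  expression vectors. The condition coefficient's *t*-test is the DC test;
  the covariate *t*-tests measure whether products depend on either gene's
  expression level, feeding the DE-dependent / DE-independent labels.

**z-scoring convention.** Genes are z-scored within each condition
separately for DC testing (so each condition's products satisfy the
identity with that condition's PCC). The survival module re-scales across
the tumor survival cohort only, after excluding the paired-design subjects,
because that cohort is the population the prognostic claim refers to.
Covariates enter the regression z-scored, not raw: the products are
themselves defined on z-scores and this keeps coefficients scale-free.

**FDR families.** Group-effect *p*-values from all pairs tested in one run
form a single Benjamini–Hochberg family. The two covariate *p*-value
columns are pooled into one family across all pairs before adjustment; a
pair is DE-dependent when either covariate's FDR falls below the cutoff
(default 0.1). Defaults: DCL calling at FDR ≤ 0.3 for the broad screen and
0.1 for reproducibility runs; both configurable. These permissive defaults
deliberately favor sensitivity in what is a hypothesis-generating screen.

**Degenerate cases.** Zero-variance genes are excluded before pair analysis
and listed in a rejects report rather than raising. A zero-variance
difference vector with nonzero mean has no finite *t* statistic; its
*p*-value is set to the smallest positive normal double and the record is
flagged `degenerate` instead of being dropped, so downstream FDR families
keep their size.

## Survival screening

For each DCL, product correlations are computed across the tumor survival
cohort and dichotomized at the across-cohort median. Values strictly above
the median are "high"; ties go to "low", a deterministic rule chosen so
that repeated runs can never split a tied stratum differently. The two
strata are compared with the standard two-group log-rank test (per
event-time hypergeometric expectation and variance, χ² with 1 df). The
statistic is implemented directly rather than delegated so the screen can
report the effect direction — the sign of observed-minus-expected deaths
in the high stratum (`worse_group`) — alongside the *p*-value; lifelines
serves as an independent cross-check in the test suite and supplies
Kaplan–Meier coordinates for export. Log-rank *p*-values are BH-adjusted
over all DCLs screened in a run; FDR ≤ 0.3 flags a prognosis DCL. Subjects
lacking either expression or survival data are dropped with a logged
count. Only right-censored overall survival is modeled; no competing risks
and no multivariate adjustment.

## Landscape diagnostics

Per pair and condition, PCCs come from the product identity. A pair is
**Strengthened** when |PCC tumor| strictly exceeds |PCC normal|, else
**Weakened**; the tie goes to Weakened, the conservative choice for the
attenuation claim. Sign patterns (differently signed / same-signed
positive / same-signed negative) treat an exact zero as positive — a
measure-zero event under the continuous model. The attenuation slope is
the OLS fit of tumor PCC on normal PCC; a slope below 1 summarizes global
correlation loss. Half-thresholding over a gene list keeps the union of
the top ⌈q·M⌉ pairs by absolute PCC in each condition (M = all pairs of
the list, default q = 0.01), admitting every pair tied at a cutoff, so
the selection can slightly exceed the nominal count. The asymmetric
heatmap matrix places normal-condition PCCs below the diagonal and tumor
PCCs above it, with identical gene order on both axes.

## Reproducibility analysis

The tumor cohort is split into *k* folds by a seeded random permutation;
with a `target_size`, folds 1..k−1 get exactly that many samples and the
last fold takes the remainder (e.g. 1093 samples at nine folds of 112
leave 85). A reference DCL set comes from one covariate-adjusted
regression run on the paired samples; each fold is then screened
(non-paired regression form) against the same normal set, and every
reference DCL earns a recurrence count in [0, *k*], stratified by
DE-dependence and sign pattern. Cross-fold concordance is the Pearson
correlation matrix between per-fold PCC vectors over the common pair
list — a diagnostic of how stable the raw correlation estimates are before
any differential claim.

## DE ranking and enrichment

Genes are ranked by sign(mean tumor − mean normal) × (−log10 *p*) from a
plain paired *t*-test (Welch's for unpaired designs); moderated-variance
models are intentionally out of scope since only the ranking, not per-gene
inference, is consumed. The signed −log10 transform of the *p*-value is a
convention choice; ties break by gene id for determinism. A gene set
(typically the DCGs — genes incident to at least one DCL) is tested with
the weighted Kolmogorov–Smirnov running sum: hits advance by
|score|^weight normalized over the set (weight default 1; weight 0 recovers
the classic KS statistic), misses retreat by 1/(G − set size), and the
enrichment score is the signed maximum deviation. Significance is a
gene-label permutation *p* = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1), two-sided
on |ES| because a DCG set could concentrate at either extreme of the
ranking; the +1 makes the smallest attainable *p* equal 1/(n_perm + 1).

## Preprocessing

Raw nonnegative expression is transformed as log2(x + pseudocount),
default pseudocount 1.0 (base and offset are conventions, configurable).
Quantile normalization maps every sample column onto the across-column
mean of order statistics, performed within a homogeneous group only (the
normal matrix and the tumor matrix separately, never across conditions);
ties within a column receive the mean of their tied target quantiles. A
single-sample matrix is returned unchanged with a warning. The operation
is idempotent in the absence of ties.

## The synthetic cohort generator

The generator emulates the statistical skeleton the analysis assumes, not
RNA-Seq realism:

- **Expression.** Log-scale values are Gaussian with SD `noise_sd`
  (default 1.0); non-planted genes are independent. Planted DC pairs are
  drawn from bivariate normals with the stated per-condition correlation;
  planted DE genes receive an additive mean shift in tumor. No
  negative-binomial count noise, library-size effects, or batches — so
  passing tests certify the inferential machinery under its model
  assumptions, not robustness to count-data artifacts.
- **Cohort structure.** `n_subjects` paired subjects contribute one normal
  and one tumor sample each; `n_extra_tumor` additional tumor-only
  subjects form the survival cohort once paired subjects are excluded,
  mirroring the analysis design.
- **Survival.** Times are exponential. For each prognosis pair, subjects
  whose product correlation (z-scored across the full tumor matrix)
  exceeds the cohort median carry hazard_ratio × baseline hazard
  (log-hazards add across pairs). Baseline hazard defaults to 1/1500 per
  day, giving median survival near 1000 days in the low stratum. Censoring
  is an independent exponential with rate baseline ×
  censor_rate/(1 − censor_rate), so the baseline stratum is censored with
  probability `censor_rate` (default 0.3). Note the analysis re-derives
  products on the cohort minus paired subjects, so its dichotomy differs
  slightly from the planting dichotomy — a deliberate touch of realism.
- **Seeding.** One integer seed drives a single generator; no helper
  reseeds internally, making cohorts byte-reproducible.

## Problem sizes in the validation suite

The test and acceptance runs use desk-scale versions of the study
conditions: calibration at 1000 null pairs / 1000 log-rank replicates,
planted-recovery at 10 true among 100 null pairs with 60 paired subjects
(20 replicates), prognosis recovery with a 200-subject survival cohort and
hazard ratio 3, attenuation fits over 1000 pairs of 300 samples, and
enrichment enumeration at G = 20 with set size 5 (15,504 candidate sets).
These sizes keep every run deterministic and fast while leaving the
binomial error bands narrow enough for the stated tolerances.

## Known limitations

- Two conditions only; no multi-group or continuous-phenotype CILP.
- OLS covariate adjustment only; no mixed models or clinical covariates in
  the DC test (the product-matrix formulation would admit them).
- The enrichment module is a single-set preranked test, not a full GSEA
  suite (no NES normalization or FDR over gene-set collections).
- Quantile normalization assumes comparable distributions within a group;
  it is not a batch-correction method.
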