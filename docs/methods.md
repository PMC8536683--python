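# Methods

This note documents the statistical models, defaults and design choices
behind `m6apattern`, in the order the pipeline runs them.

## Input model and preprocessing

Expression is a dense genes x samples matrix tagged FPKM, TPM or LOG2.
FPKM is converted by per-column renormalization, TPM_ij = FPKM_ij /
sum_i(FPKM_ij) * 1e6, so every sample sums to one million. All downstream
statistics assume roughly symmetric values, so non-log input is
log2(x+1)-transformed exactly once at pipeline entry. Gene identity is the
case-sensitive symbol string; duplicate rows collapse by arithmetic mean
before any unit conversion (deterministic and order-independent). Samples
without overall-survival time or status are dropped with a logged count;
other missing covariates propagate as NaN.

The regulator catalog packages the 23 m6A regulators — 8 writers, 13
readers, 2 erasers — as a typed constant; downstream code takes any gene
panel, so the catalog is a default, not a constraint.

## Consensus clustering

Samples are z-scored per gene using full-cohort mean/sd (per-resample
standardization destabilizes small subsamples), then for each candidate k
and each of 1000 resamples, ceil(0.8 * n) samples are drawn without
replacement and clustered by k-means (k-means++ initialization, 10
restarts, best inertia). The consensus matrix entry for a pair is its
co-assignment count over its co-sampling count; pairs never co-sampled
(negligible probability at 1000 resamples) get 0 with a warning. Final
assignments cut an average-linkage dendrogram of 1 - consensus. The inner
k-means is a small vectorized in-package implementation because a run
issues ~50,000 tiny fits and per-call overhead dominates; it is verified
against scikit-learn's KMeans in the tests.

**Cluster-number selection.** The consensus CDF area A(k) and its relative
change (delta-area) are recorded as the stability curve, but they do not
decide k: at these problem sizes the delta-area curve is dominated by the
mechanical growth of A(k) with k and is nearly identical for structured
and structureless data (we measured delta curves of 0.50/0.30/0.14/0.08
for planted three-cluster data versus 0.50/0.33/0.13/0.07 for pure noise).
Selection instead uses the proportion of ambiguous clustering, PAC: the
fraction of off-diagonal consensus entries in (0.1, 0.9). A k counts as
stable while PAC <= 0.2 (the conventional boundary of the "mostly
unambiguous" regime); the chosen k is the largest k in the stable prefix
of the k range. On structureless data no k is stable and the delta-area
elbow (threshold 0.1, ties toward smaller k) decides as a fallback. With
three planted subtypes, PAC(3) <= 0.12 and PAC(4) >= 0.25 across seeds, so
k = 3 is selected with a wide margin, while null cohorts flag no stable k.

## Single-sample enrichment

**ssGSEA.** Within each sample, genes are ranked by expression (average
ranks on ties) and walked in descending order; the enrichment score is the
summed difference between the rank^alpha-weighted in-set ECDF and the
uniform out-of-set ECDF, with alpha = 0.25. By default the whole score
matrix is normalized by its global range. Scores depend only on
within-sample ranks, hence are invariant to any strictly monotone
per-sample transform.

**GSVA-style scores.** Each gene's expression is converted to a Gaussian
kernel CDF across samples (bandwidth sd/4, floored at 1e-8 for constant
genes, with a warning), ranked per sample, and folded into the symmetric
statistic |rank - p/2|. A KS-like walk down the ranking with in-set weight
|r|^tau (tau = 1) yields the score: maximum positive plus maximum negative
deviation (`mx_diff`, the default) or the maximal absolute deviation.
Scores are bounded in [-1, 1]; a set equal to the whole gene universe
degenerates to 0 with a warning.

Group contrasts of enrichment scores reuse the moderated t machinery below
and report logFC / AveExpr / t / p / adj_p per set.

## Differential expression

The moderated two-sample t shrinks per-gene pooled variances toward a
prior: with residual df d_g, the prior (d0, s0^2) is estimated by
moment-matching log s_g^2 to a scaled F distribution via trigamma
inversion, and the posterior variance is (d0 s0^2 + d_g s_g^2)/(d0 + d_g);
t is referenced to d0 + d_g df. If the log-variances are underdispersed
the inversion has no solution and the test falls back to the ordinary
pooled t (d0 = infinity) with a warning. Type-I error on 5000 null genes
at n = 10/10 is 0.050 +/- 0.01 (checked in the acceptance suite).

Phenotype DEGs run the moderated t over all cluster pairs; the default
keeps genes BH-significant (adj_p < 0.05) in at least one pair (UNION —
the permissive reading; INTERSECT available). Both raw and adjusted p are
emitted.

Kruskal-Wallis, one-way ANOVA, and the Wilcoxon rank-sum wrap scipy.stats
(tie-corrected, two-sided). BH adjustment is the step-up rule with
monotonicity enforcement, order-invariant, verified against both the
sorted-definition oracle and statsmodels. Distance correlation uses the
double-centered pairwise-distance formula with a seeded permutation
p-value (999 permutations by default).

## Survival analysis

Kaplan-Meier is the product-limit estimator with ties handled as
simultaneous events; the median is the first time S(t) <= 0.5. The k-group
log-rank test accumulates observed-minus-expected events with the
hypergeometric (tie-corrected) covariance and refers (O-E)' V^- (O-E) to
chi-square on k-1 df.

Cox proportional hazards maximizes the partial likelihood by
Newton-Raphson (max 50 iterations, gradient tolerance 1e-8, step-halving
ascent guarantee), with Breslow tie handling by default and Efron as an
option; both are verified against lifelines. Wald CIs and p-values are
reported; non-convergence returns the last iterate with `converged=False`,
and |beta| > 20 flags monotone likelihood (separation) rather than
silently clipping. Constant or collinear covariate columns are errors.
In the multivariate model, stage enters as ordinal 1-4 and gender as 0/1.

The score cutpoint maximizes the absolute standardized two-group log-rank
statistic over midpoints of consecutive distinct score values whose split
keeps both groups at >= minprop (default 0.1) of the cohort; ties resolve
to the smallest cutpoint. The maximal statistic's p-value is NOT corrected
for the search: the cutpoint only dichotomizes, and the reported group
difference is the ordinary log-rank on the chosen split, which is
optimistic — a documented caveat, matching common practice. Exactness is
guaranteed by an exhaustive-scan oracle test at n <= 60. Note that with
two constant-hazard halves the chosen cut can drift off the half boundary
(noise optima of the strongly correlated z-process); the induced
partition, not the cut coordinate, is the reliable output.

## The m6Ascore

Signature genes are the phenotype DEGs that pass a per-gene univariate Cox
screen on standardized expression (raw Wald p < 0.05 by default, matching
the permissive "significant prognostic value" reading; the null survival
fraction of the screen is calibrated to the threshold within +/- 0.02).
The surviving genes are z-scored; PCA is taken by SVD of the samples x
genes matrix (correlation-PCA, samples as observations); the score is
PC1 + PC2 per sample.

PCA is sign-ambiguous, so each axis is flipped, if needed, to make the
summed loading of protective genes (Cox beta < 0) positive; if that sum is
exactly zero the largest-|loading| gene anchors instead. This makes the
score fully deterministic and oriented "high = protective", which fixes
the direction of every downstream contrast (HIGH group HR < 1, TMB
anticorrelation, response advantage). Dichotomization uses the maximal
log-rank cutpoint above; HIGH means score strictly above the cutpoint.

## Mutation and immunotherapy summaries

TMB counts records whose variant class is in the conventional
nonsynonymous MAF set (missense, nonsense, frameshifts, splice site,
in-frame indels, translation start, nonstop) divided by an exome size of
38 Mb (configurable; all score-TMB statistics are scale-invariant in this
divisor). Gene-level mutation frequency counts a sample once per gene; the
panel-level frequency is the fraction of samples with >= 1 mutation in any
panel gene. CNV summaries report per-gene fractions of positive (gain) and
negative (loss) integer calls. Score-group comparisons report the Wilcoxon
rank-sum on TMB plus each group's any-mutation fraction.

Immunotherapy response scores are consumed as-is on an arbitrary ordinal
scale (no re-derivation of upstream immunophenoscore algorithms),
stratified by the four anti-CTLA4/anti-PD-1 treatment flags; HIGH-vs-LOW
contrasts use the Wilcoxon rank-sum, as do the CD80/CD86 checkpoint-ligand
expression contrasts.

## Synthetic cohort generator

The generator emits one pre-integrated log2-scale matrix (multi-cohort
merging is the user's responsibility) with 600 samples in three subtypes
(proportions 0.45/0.18/0.37), gene baselines U(2, 8), and i.i.d. Gaussian
noise (sd 1.0). Planted structure:

- **Regulator blocks** (shift +1.2): subtype A up-regulates METTL14,
  RBM15, YTHDC1, YTHDC2, FMR1, HNRNPA2B1; B up-regulates IGFBP1, IGFBP3;
  C up-regulates RBM15B, YTHDF2, IGFBP2, FTO, ALKBH5.
- **Latent prognosis score.** Each sample's log hazard is
  h(subtype) - g with h = (-0.5, +0.8, -0.3) for (A, B, C) and
  g ~ N(0, 0.5) a continuous protective frailty; the latent score is the
  negated log hazard, so it contains a "subtype B is high-risk" component
  plus a continuous part. Event times are exponential with baseline median
  36 months; censoring is Uniform(0, c) with c solved by root-finding so
  the expected censored fraction equals 0.5.
- **Phenotype genes** (90, three equal blocks): each block shifts +1.0 in
  its subtype (making the blocks recoverable as DEGs) and additionally
  loads +/- 0.4 on the standardized latent score (positive for the A and C
  blocks, negative for the B block). The loading matters: the m6Ascore is
  computed from expression, so without it the continuous score reflects
  only the dominant A-vs-C mean contrast and none of the within-subtype
  prognosis — the B-lowest-score and score-TMB/response couplings then
  fail even though every cluster-level analysis works.
- **Immune signatures**: 48 synthetic immune genes plus CD80/CD86, all
  shifted +1.0 in subtype A (the good-prognosis, immune-rich pattern),
  grouped into six signature sets; four toy pathway sets (immune,
  oncogenic, metabolic, background) support the GSVA stage.
- **Mutations**: per-sample nonsynonymous counts are negative binomial
  (size 2 — overdispersion typical of TMB) with mean 40/120/60 by subtype,
  scaled by exp(-0.35 g) within subtype; genes draw from regulators (25%
  of mass, ZC3H13 weighted 4x) and background genes; ~15% extra Silent
  records are appended. CNV calls give amplification-trend regulators
  gain/loss probabilities 0.25/0.05 and deletion-trend regulators the
  reverse.
- **Response**: stratum assigned uniformly over the four treatment flags;
  response score = 0.8 * standardized latent + N(0, 1). The 0.8 effect is
  an artifact constant chosen once (the response scale is ordinal and
  arbitrary).

Everything derives from a single seed; the same config is byte-identical
across runs. What the generator does **not** emulate: cross-cohort batch
effects, gene-gene correlation beyond the planted blocks, realistic
mutation spectra or CNV segment structure, and non-proportional hazards.
Passing tests therefore demonstrate that the pipeline recovers the stated
structure under idealized noise, not performance on real cohorts.

## Problem sizes and verification

The acceptance suite runs the full consensus procedure (1000 resamples, k
in 2..6) on one default cohort and the score chain on 20 cohorts of 600
samples; calibrations use 5000 genes, and Cox recovery uses n = 2000 with
a planted log-HR of 0.7 (the acceptance script averages 5 independent
fits, since a single fit's Monte-Carlo sd is ~0.07). One caveat is
measured and accepted rather than hidden: with the default planted effect
size, the supervised oracle that knows the true class means reaches ARI
0.80 against the planted labels, so unsupervised consensus clustering
(typically 0.75-0.79) operates at the Bayes ceiling; the cluster-number
selection is nevertheless stable at k = 3.

## Known limitations

- The inner clusterer is k-means (spherical clusters after z-scoring);
  strongly elliptical or nested structure would favor PAM/hierarchical
  inner loops.
- GSVA uses the Gaussian kernel only (no Poisson kernel for counts) and no
  permutation p-values for enrichment scores.
- The Cox implementation has no time-dependent covariates, stratification,
  or robust variance.
- The cutpoint p-value optimism is documented but not corrected; treat the
  HIGH/LOW log-rank p as descriptive.
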