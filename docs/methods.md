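# Methods

This note documents the statistical machinery, the defaults and the design
choices made where the design was genuinely open, in the order the
pipeline runs.

## Design and coding

The experiment is a balanced two-level full factorial (default factors
Salinity, Sediment, Flow; 8 replicates per cell, 64 libraries). Factors
are treatment-coded (ambient = 0, treated = 1), so a main-effect
coefficient is the log2 fold change (LFC) of that stressor at ambient
levels of the others, and interaction coefficients are deviations from
log-additivity. Model-matrix columns are ordered Intercept, mains,
pairwise, three-way, then surrogate covariates; interaction columns are
elementwise products of their parents and the matrix must be full rank.

## Synthetic data generator

The generator emulates transcript-level *estimated* counts as produced by
abundance estimation, not reads:

- **Truth.** Per gene: baseline `beta0 = log2` mean at all-ambient, drawn
  log-uniform in [5, 5000] counts (spanning the expression-filter
  boundary); dispersion log-normal with median 0.1 and sdlog 0.5 (typical
  bulk RNA-seq); a latent batch loading `gamma` (|gamma| ≈ 1 log2 unit) on
  30% of genes. 5% of genes get one signed main effect and 5% one signed
  interaction (magnitudes |N(1, 0.25²)|, floored at 0.3 so classes are
  well defined); interaction genes are constructed so that the injected
  S+/S−/A+/A− label is exactly re-derivable from the true coefficients.
- **Counts.** Gene means are `s_j · 2^(x'beta + gamma·batch_j)`; counts
  are gamma-Poisson (negative binomial) with the gene's dispersion, with a
  Poisson branch for dispersions ≤ 1e-10. Size factors are log-normal
  (sdlog 0.2), rescaled to geometric mean 1.
- **Batch.** One binary batch assigned by replicate parity within each
  design cell, hence exactly crossed with (orthogonal to) the design; this
  makes surrogate recovery identifiable and lets the frozen correction be
  scored without touching design contrasts.
- **Isoforms.** 1–4 isoforms per gene, lengths log-uniform in [300, 5000]
  bases, per-gene Dirichlet(1) usage weights fixed across samples; gene
  counts are partitioned across isoforms, so transcript counts are
  non-negative reals whose gene sums are the simulated counts.

What the generator does *not* emulate: read-level noise, mapping
ambiguity, varying isoform usage across conditions, correlated genes,
library-preparation artefacts beyond a single global batch, and
mean-dispersion trends (dispersions are drawn independently of means).
Passing recovery tests therefore demonstrates correctness of the inference
chain under the assumed model, not robustness to real-data pathologies.

## Preprocessing

- **Gene summarisation.** Gene count = sum of member-transcript estimated
  counts (conserves per-sample totals to machine precision). Gene
  effective length = weighted mean of member lengths with weights
  proportional to count/length (isoform-abundance weights), unweighted
  mean when all members are zero in a sample. Effective lengths are
  carried for round-trip checks only; the GLM uses size factors alone —
  within a single species, per-gene length offsets cancel across samples
  to first order. Recorded as a limitation for cross-feature comparisons.
- **Size factors.** Median-of-ratios against the per-gene geometric-mean
  reference over genes positive in all samples, then rescaled to geometric
  mean 1 (the rescaling is a convention; ratios are unchanged).
- **Filter.** Keep genes with ≥ 10 normalised counts (count/s_j) in ≥ 8
  samples. Normalisation is applied after gene summarisation and before
  filtering.
- **VST.** `log2(count/s + 1)`: monotone, dispersion-free, adequate for
  the clustering and correction downstream; an exact variance-stabilising
  transform is deliberately out of scope.

## Surrogate variables

Hidden variation is estimated from the residuals of the VST matrix after
regressing out the full factorial design (reduced model: intercept only).
The number of surrogates k is chosen by parallel analysis: the variance
share of each leading right-singular vector of the residual matrix is
compared with the (1 − alpha) quantile (alpha = 0.05) of shares obtained
after permuting each gene's residuals independently across samples
(n_perm = 100, seeded); counting stops at the first non-significant
component. The surrogates are the corresponding right-singular vectors —
zero-mean (the intercept is in the design) and mutually orthogonal. This
is a deliberate simplification of iteratively reweighted surrogate-variable
analysis: one pass, no gene weighting; it recovers a crossed batch with
|r| > 0.99 in the standard simulation.

Frozen correction for visualisation/clustering fits per-gene OLS on
[design | surrogates] and subtracts only the surrogate contribution,
retaining design-attributable signal. Collinearity between surrogates and
design columns is an error, not silently tolerated.

## Negative-binomial inference

- **Fitting.** Per-gene NB GLM with log link and offset `log s_j`,
  maximised by Fisher-scoring IRLS, batched across genes; convergence when
  max |Δbeta| < 1e-8 (natural-log scale), cap 100 iterations. Non-converged
  genes are flagged, never dropped. Non-intercept coefficients are clamped
  to ±10 log2 units (separation guard for all-zero treatment groups) and
  flagged when the clamp engages. Real-valued estimated counts are
  supported throughout (gamma-function likelihood). Standard errors come
  from the observed-information covariance; coefficients are reported in
  log2 units.
- **Dispersion.** Start: method of moments from Pearson residuals of a
  Poisson fit, `alpha = max(1e-8, (Σr² − df)/Σmu)`. Refinement
  (default on): maximise the Cox–Reid adjusted profile likelihood on a
  13-point log grid spanning ×1/8…×8 around the start, with parabolic
  interpolation and grid re-centring when the optimum lands on an edge.
  Moderation (default on, needs ≥ 100 genes): DESeq2-style empirical
  Bayes — fit a trend `a0 + a1/mean` by trimmed least squares, set a
  log-normal prior whose variance is the across-gene spread of
  log-dispersions in excess of the expected sampling noise
  (`trigamma(df/2)`, floored at 0.25²), and take the MAP on the same grid;
  genes more than 2 prior-sd above the trend (dispersion outliers) keep
  their unshrunk estimate. Rationale: with purely per-gene estimates the
  sampling noise of the plug-in dispersion inflates the extreme tails of
  the Wald statistics (measured ×1.4–1.9 at p ≤ 0.001 under the global
  null, versus conservative tails at the true dispersion), which is fatal
  exactly where BH thresholds for sparse-signal families sit.
- **Testing.** Wald statistic `beta/SE`. The pipeline evaluates it against
  a Student-t reference with `df = n − p` — the plug-in dispersion makes
  the statistic's true tails heavier than normal, and at depth p ≈ 1e-4
  the t(55) tail exceeds the normal one by ~2.7×; with the t reference the
  pooled empirical FDR at nominal 0.1 is 0.09–0.11 in the standard
  simulation versus up to 0.16 with the normal reference. The standalone
  `wald_test` keeps the classical normal reference by default, with `df`
  as an explicit argument. BH adjustment is applied per model term across
  genes (7 term-wise families, matching per-treatment DE lists); the
  significance threshold is adjusted p < 0.1.
- **Shrinkage.** Adaptive shrinkage of each term's LFCs: zero-centred
  scale-mixture-of-normals prior (point mass at 0 plus a geometric grid of
  component SDs from min(SE)/10 to 2·max|beta|, ratio √2), mixture weights
  fitted by EM on the marginal likelihood of beta|SE (tolerance 1e-8, cap
  1000 iterations), posterior means reported. Shrinkage is fitted per term
  (whether the original analysis pooled terms is unknowable; per-term keeps
  the families aligned with the testing families). Shrinkage never
  increases a coefficient's magnitude.

## Interaction classification

Expected combined LFC: sum of main effects for a pair; sum of all six
lower-order terms for the triple (the all-lower-order convention for the
three-way expectation is a choice — the verbal definition does not pin it
down). Classification uses the raw (unshrunken) coefficients of genes
whose interaction term passes FDR < 0.1: sign(expected) × sign(interaction)
→ {S+, A+, S−, A−} as in the README table. When |expected| < 1e-6 the
deviation is synergistic by convention (S+ if the interaction is positive,
S− otherwise); interactions within 1e-6 of zero are a caller error.
Tabulation follows the report layout (classes × combinations, with
per-combination totals). Exclusive DE-set intersections assign each gene
to its full membership signature (UpSet semantics); the treatment
dendrogram uses average-linkage agglomeration of Euclidean distances
between treatment columns of the shrunken-LFC matrix, with
non-significant entries zeroed (not dropped) so the distance matrix stays
complete.

## Profile clustering

Genes with any significant interaction are z-scored per gene across
samples on the frozen-corrected VST matrix (constant genes become zero
rows and are flagged), averaged over the 8 design cells, and clustered by
correlation distance under average linkage. The cut maximises the mean
silhouette over k ∈ [2, 8]; if all pairwise cell-profile correlations
exceed 0.8 the genes are treated as one shared shape (silhouette cannot
express "one cluster", and splitting pure noise otherwise scores
spuriously well). Clusters below the minimum size (default 10) are
dissolved to an explicit unassigned pool in a single pass — members +
unassigned always equals the input. Determinism is fixed by sorting genes
by id before clustering.

## Enrichment

Annotations are propagated up the child→parent term DAG under the
true-path rule (set semantics; cycles are an error naming the cycle).
Each term is scored by the one-sided hypergeometric upper tail
(over-representation only) against the universe of all genes tested for
differential expression. The elim variant decorrelates the DAG: terms are
visited leaves-first (lexicographic topological order for determinism);
when a term's current p < alpha_elim (default 0.01) its study genes are
removed from all ancestors before those are tested; raw and elim p are
both reported, with no multiple-testing correction across terms (the
source convention). The hybrid weighting variant is deliberately not
implemented — elim is fully specified and testable.

## Pipeline & determinism

`run_pipeline` executes simulate/load → fit → interactions → profiles →
enrichment, writing every intermediate TSV, a timestamped log, and a
`manifest.json` (config, seed, version, per-stage row counts) that is
bit-identical across identical config + seed. Any stage failure writes a
`FAILED` marker naming the stage and preserves completed artifacts. All
randomness flows from a single seed through `numpy.random.SeedSequence`
spawning.

## Problem sizes used in validation

The seeded validation suite uses 2,000 genes × 64 samples for null
calibration (20 replicates for false-call rates), 1,000 genes × 64 × 20
replicates for FDR/sensitivity/class recovery, 800 genes for surrogate
recovery, and 40 + 5 genes for clustering recovery — sizes at which every
metric is stable across seeds while the whole suite remains quick on one
CPU.

## Known limitations

- Fits are not exactly invariant to rescaling one sample's counts and size
  factor jointly: the rescaled sample carries proportionally more Fisher
  information under any count likelihood, so the MLE legitimately shifts
  (observed ~1e-2 at most in the factorial fits); normalised counts, and
  hence the targets of inference, are unchanged.
- No outlier handling (Cook's-style replacement) and no likelihood-ratio
  tests; no independent filtering of the FDR.
- Gene effective lengths do not enter the GLM (single-species design);
  cross-gene expression comparisons are out of scope.
- The surrogate estimator assumes batch-like structure is orthogonal
  enough to the design to survive residualisation; a batch confounded with
  a design factor is not recoverable and will be silently absorbed.
- Biological pooling of individuals within a library is modelled only
  implicitly through the dispersion.
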