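# Methods

## Model

For gene g and stacked column i (one of n samples counted by one of k
aligners, n·k columns in total) the counts are modelled as negative
binomial, `Var = mu + phi*mu^2`, with log link and offset:

    log(mu_gi) = x_i' beta_g + log(N_i)

`x_i` contains an intercept plus treatment-coded contrasts for the
experimental group factor and the mapper factor — additive, no
interaction. The reference level of each factor is the lexicographically
smallest, which makes coefficients and outputs deterministic across runs
and platforms. `N_i` is the effective library size (column sum × TMM
factor). A gene is a *difficult gene* (DG) when the likelihood-ratio tests
for the mapper factor **and** the group factor are both significant after
Benjamini–Hochberg adjustment (adjustment applied separately per factor,
across genes). A raw-p-value mode exists behind a flag.

The additive model deliberately has no mapper×group interaction: the
question is whether the aligner shifts a gene's measured level at all, not
whether it does so differently per group. Consequently a gene whose
aligner bias is exactly group-dependent with zero main effect would be
missed; this is accepted as out of scope.

## Preprocessing

* **Filter**: gene dropped iff the fraction of columns with count < 5 is
  strictly greater than 30% (a gene at exactly 30% is kept). On the
  stacked table the rule is applied over all n·k columns jointly — the
  combined table is the analysis unit; a per-mapper filter mode exists for
  the single-aligner DEG workflow, which refilters its own table.
* **TMM**: for each column against a reference column (the one whose
  75th-percentile of scaled counts is closest to the mean of those
  percentiles), per-gene log-ratios M and mean log-abundances A are
  computed over genes nonzero in both columns (no pseudocounts), doubly
  trimmed (30% tails on M, 5% tails on A, average-rank ties), and combined
  as a mean of M weighted by inverse delta-method variances
  `(L-y)/(L*y)` summed over the two columns. Factors are rescaled to
  geometric mean 1. Columns where fewer than 10 genes survive trimming
  fall back to factor 1 with a warning. The implementation reproduces the
  reference TMM (edgeR `calcNormFactors`) to ~1e-6 on shared fixtures.
  Note the precision weights are not exactly scale-free, so multiplying
  one column by a constant perturbs factors at the ~1e-3 level; M-values
  and trimming themselves are exactly invariant.

## Fitting and testing

* **IRLS**: working weights `mu/(1+phi*mu)`, offset log link; convergence
  when the relative deviance change is below 1e-8 *and* the largest
  coefficient step is below 1e-9 (the second criterion tightens the final
  iterate to ~1e-8 coefficient accuracy, verified against Nelder–Mead
  maximization of the written-out likelihood); cap 100 iterations;
  coefficients clamped to |beta| <= 50 to guard all-zero genes, which are
  returned flagged degenerate. Fitting is vectorized across genes (batched
  normal equations), so a 2000-gene × 30-column analysis takes ~1 s.
* **Dispersion**: Cox–Reid adjusted profile likelihood
  `APL_g(phi) = ll_g - 0.5*logdet(X'WX)` evaluated on a 25-point
  log-spaced grid over [1e-6, 10]; the per-gene maximum is located by
  quadratic interpolation around the best grid point (this realizes the
  1-D optimization over log-dispersion in a form that vectorizes). The
  common dispersion maximizes the mean APL; gene-wise estimates maximize
  `df_res*APL_g + prior_df*mean(APL)` with prior_df = 10 by default, so
  prior_df → ∞ collapses every gene to the common value. All-zero genes
  receive the common value. Dispersion is estimated once under the full
  model and reused for the reduced fits — the tests concern the mean
  model.
* **LRT**: `2*(ll_full - ll_reduced)` clipped at 0, chi-square reference
  with df = rank difference; non-converged genes get p = 1 and a flag. On
  null simulations at the default study conditions the raw rejection rate
  at 0.05 is ≈ 0.05 for the group factor and ≈ 0.055 for the mapper
  factor (the mild liberality of tagwise-dispersion LRTs at n·k = 30 is
  shared with the reference GLM implementation).
* **Exact test** (two-group, single-aligner DEG calling): counts are
  mapped to the geometric-mean effective library size by a first-order
  moment match (mean and NB variance matched under the gene's pooled
  proportion, clipped at 0 — identity when sizes are already equal; the
  reference implementation interpolates gamma quantiles instead), group
  sums rounded to integers, and the two-sided p-value computed by
  enumerating all partitions of the total: group sums of i.i.d. NB
  variables with a common mean are NB with size n/phi, and conditional on
  the total the partition law is mean-free. All partitions with
  probability ≤ that of the observed one (minimum-likelihood rule,
  relative tolerance 1e-10 for ties) are summed. phi = 0 yields the
  Poisson/binomial limit. Verified exactly against brute-force enumeration
  for totals ≤ 200.

## Ranking and summaries

Genes are ordered by (padj_mapper ↑, padj_group ↑, gene_id ↑); the id key
makes ties deterministic. Per-mapper summary percentages are computed with
DG_m = DG ∩ DEG_m: `pct_dg_of_all = 100*|DG_m|/G_kept` and
`pct_dg_of_deg = 100*|DG_m|/|DEG_m|` (NA when the DEG list is empty); the
unconditional `100*|DG|/G_kept` is also emitted as `pct_dg_total` since
"share of all genes" is ambiguous between the two denominators.

## Annotation features

From an Ensembl-dialect GTF (1-based inclusive coordinates, strand
ignored): per transcript, exon lengths `end-start+1`, exon count, and
mature transcript length (sum of exon lengths — the RNA-seq convention;
the genomic span is also emitted); per gene, the median of each
transcript-level statistic plus the transcript count. `is_pseudogene` is a
substring match of "pseudogene" in `gene_biotype` (covers processed/
unprocessed/unitary variants); `is_coding` requires exactly
`protein_coding`. Group profiles report within-group medians and
integer-rounded biotype percentages.

## Classification protocol

Panels of `floor(n/3)`, `floor(n/2)`, `floor(2n/3)` genes (n = samples)
are evaluated by stratified k-fold cross-validation — k = 5 for n ≤ 20,
else 10 (the boundary n = 20 is assigned to 5-fold) — repeated 10 times
with seeds derived from one master seed. Inside each training fold the
candidate list is re-ranked by the one-way F statistic on training samples
only before the top panel is taken, so selection never sees test data
(enforced by a test that spies on the selection call). Four base learners
— RBF-SVM with Platt probabilities, 500-tree random forest, one-hidden-
layer (5-unit) MLP, CART tree; SVM/MLP behind a standardizer — are each
refit on 100 within-class bootstrap resamples (resampling per class keeps
every class represented); the ensemble averages class probabilities over
all 4×100 fits, ties broken toward the lexicographically first class.
Reported: per-repeat misclassification % over the pooled CV predictions
and the mean AUC (standard two-class AUC with ties counted 1/2; mean of
pairwise one-vs-one AUCs for more classes, matching the usual multiclass
ROC construction). All ensemble sizes are configuration fields; the test
suite and the acceptance script run reduced ensembles (3–5 bootstraps,
50-tree forests, 2–10 repeats) chosen as the package's own economical
defaults for property checks, while the protocol defaults above remain
the package defaults.

## Simulator

`simulate(SimConfig)` draws NB counts forward from the model: baseline
log2-means uniform on [3, 10] (typical filtered bulk RNA-seq abundances),
per-(mapper, sample) library-size factors log-uniform on [0.5, 2] (the
spread of assigned-read totals across aligners and libraries), gene-wise
dispersion 0.1 by default, and disjoint gene sets carrying a group effect
only, a mapper effect only, or both (the planted DGs), with |log2FC| = 2
and random signs. The mapper effect lands on the last-named aligner,
mimicking one aligner systematically over- or under-counting a gene
subset; the group effect lands on the last group. Outputs are
byte-deterministic given the seed.

What the simulator does *not* emulate: correlated biases across aligners
(real aligners disagree in correlated, sequence-driven ways), positional
coverage structure, gene–gene count correlations, outlier samples, and
composition effects large enough to stress TMM. Passing the recovery and
calibration checks therefore shows the procedure is correct under its own
distributional assumptions, not that real-data DG percentages are
reproduced — those depend on the aligners, annotation and datasets used.

## Degenerate and edge cases

* Literally duplicating one aligner's table under two mapper labels gives
  an exact zero mapper-effect MLE, hence LRT statistics 0 and p-values 1
  for every gene: the DG set is empty (conservative), and the uniformity
  of mapper p-values is instead a property of *exchangeable* aligner
  columns (independent draws from the same law), which is what the null
  simulation checks.
* All-zero genes: flagged, fitted at the clamp, assigned the common
  dispersion; empty filter results warn and return empty objects; empty
  DEG lists make the DEG-conditional percentage NA.

## Known limitations

The chi-square reference for the LRT and the APL grid resolution are
asymptotic/discrete approximations; with very few samples per group or
dispersions at the bounds the tests inherit the usual small-sample
liberality. The exact test's moment-matched size adjustment is a
first-order approximation, adequate for the modest size spreads TMM
leaves. The classifier assumes at least two samples per class per fold
and reduces k when a class is smaller than k.
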