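# Methods

This note documents the statistical machinery, the synthetic-data model, the
numerical choices, and the known limitations of `ddcpredict`.

## Moderated differential expression

For a two-group contrast the per-gene statistic is a moderated *t*: the pooled
sample variance `s2_g` (residual df `d = n1 + n2 - 2`) is shrunk toward a
prior `s0^2` with prior df `d0`, giving the posterior variance
`(d0*s0^2 + d*s2_g) / (d0 + d)` and a *t* reference distribution on `d + d0`
df.  The hyperparameters are fitted by method of moments on
`e_g = log(s2_g) - psi(d/2) + log(d/2)`: the mean of `e_g` identifies
`log(s0^2)` and the excess of its variance over `psi'(d/2)` identifies
`psi'(d0/2)` (solved by Newton iteration on the trigamma function).  When the
observed log-variances are under-dispersed relative to `psi'(d/2)` the prior
df is infinite and all genes share `s0^2`.  Setting `prior_df = 0` recovers
the ordinary pooled *t* exactly, which is the limit the tests pin down.
Zero-variance genes are floored at the smallest positive variance with a
warning.  Significance is BH `q < 0.05` with no logFC threshold; a
`|logFC| >= 1` threshold is applied only when summarising response DEGs per
cluster.  The model is a plain two-group contrast without covariates.

Label-inconsistent samples are flagged by average-linkage hierarchical
clustering on `1 - Pearson` distance over DEG genes, cut at two clusters
(the disease/control argument is binary); each cluster takes its majority
label and dissenting samples are returned.  The linkage and distance are a
stated reconstruction — the choice is not uniquely determined by the original
heatmap argument.

## MCODE and hub centralities

MCODE vertex weight is `k * density` of the densest k-core of the closed
neighborhood; complexes grow outward from the highest-weight unvisited seed,
admitting neighbors with weight at least `(1 - vwp) * seed weight`
(`vwp = 0.2`), to a depth cap of 100.  Haircut (on by default) reduces a
module to its 2-core; fluff (off) would add boundary nodes whose closed
neighborhoods are dense.  A vertex belongs to at most one module.  Module
score is `density * node count`, so an isolated clique of size `n` scores
`n`.  The signature ("disease-defining genes") is the union of the top
passing module per direction under score > 3 and node count > 5; taking all
passing modules is a config option, with one module per direction the
default.

Centralities: degree; MNC, the node count of the largest connected component
of the open-neighborhood subgraph (ties broken by edge count, then smallest
member symbol); DMNC, `|E| / |V|^eps` of that same component with
`eps = 1.7` (the exponent of the original density-of-MNC proposal; the method
is named in the source analysis without parameters); MCC, the sum of
`(|C| - 1)!` over maximal cliques `C` containing the node, with `0! = 1` for
isolated nodes; EPC, a Monte-Carlo edge-percolation score — each trial draws
a retention probability uniformly on (0,1), keeps each edge independently
with that probability, and credits the node with its surviving component
size; the score is the mean over trials (100 by default in tests, 1000 for
runs; deterministic given the seed).  The per-trial uniform retention scheme
is a stated reconstruction of the published tool's percolation, which does
not document its scheme.  Top-10 membership per method is tallied after
removing genes with degree < 10; top-k ties break by descending degree, then
symbol.

## ssGSEA and the permutation null

Genes are ranked by decreasing expression within each sample (ties broken by
symbol), rank `r = N .. 1`.  The score is the sum over all ranked positions
of the difference between the weighted in-set CDF (weights `r^alpha`,
`alpha = 0.25`, the canonical exponent) and the uniform out-of-set CDF.
Because rank `r_g` counts the positions whose running sum includes gene `g`,
the sum collapses to

    sum_{g in S} r_g^(1+a) / sum_{g in S} r_g^a  -  sum_{g not in S} r_g / (N - |S|),

which turns scoring into one boolean-matrix product per matrix — this is what
makes the 1000-set permutation null cheap.  Scores are rank-based and hence
invariant under any strictly monotone transform of the expression values.  No
cross-sample rescaling is applied; scores are only ever compared within a
dataset (whether the original analysis rescaled before its rank-sum
comparisons is unstated; raw scores are used here).

The permutation null draws `n_perm = 1000` same-size gene sets uniformly
without replacement from the matrix's measured-gene universe, records each
set's case-minus-control mean score difference, and reports
`empirical_p = (1 + #{background >= observed}) / (n_perm + 1)` (add-one, so
the p-value is never zero) alongside the observed Wilcoxon rank-sum p.  The
rank-sum test uses exact enumeration when both groups have n <= 8 without
ties and a tie-corrected normal approximation otherwise.

## Disease-defining clusters

Each retained dataset contributes one column of Spearman correlations
(Pearson on mid-ranks) between the signature's per-sample ssGSEA score and
each panel gene.  A dataset missing more than `max_missing = 5` signature
genes is excluded with a recorded reason (the rule that removed a blood
cohort with six missing genes).  Missing per-gene entries are row-mean
imputed at clustering time rather than dropped, preserving panel coverage.
Rows are clustered by K-means (Lloyd + k-means++, best of 25 restarts by
WSS; delegated to scikit-learn, whose k-means++ cannot produce empty
clusters, so no re-seeding path is needed).  Rows are not standardized before
clustering — ρ is already bounded — with a config switch to enable it.

k is fixed at 8 by default, or chosen as the **second elbow** of the WSS
curve over k = 1..15: elbows are local maxima of the discrete second
difference `WSS(k-1) + WSS(k+1) - 2*WSS(k)` restricted to positive
curvature, taken in increasing k; if fewer elbows exist the last one is
returned with a warning.  The second-difference rule is a reconstruction of
an informally described elbow criterion.  The total WSS at the chosen k is
logged, not enforced — its published "< 100" bound is scale-dependent.

## Response models

Per cluster: features are the cluster's panel genes; an 8:2 stratified split;
SMOTE (Chawla-style: a synthetic minority sample interpolates between a
random minority point and one of its k = 5 nearest minority neighbors with a
single uniform weight per vector) balances the training classes 1:1; then L1
logistic regression over a 30-point geometric lambda path from
`lambda_max = max |X'(y - ybar)| / n` down to `0.01 * lambda_max`, tuned by
stratified ten-fold cross-validated binomial deviance.  The deviance-minimum
lambda is the default (it reproduces the reference behaviour of selecting
roughly half the cluster's genes); a 1-SE rule is available.  Features are
standardized internally and coefficients reported on the original scale.  The
solver (saga) leaves the intercept unpenalized, so at the head of the path
the model is exactly the null model with intercept equal to the empirical
log-odds.  SMOTE operates on raw features before standardization (the
ordering is unstated in the source analysis; this choice keeps synthetic
points in expression units).

Evaluation: Mann-Whitney AUC (ties half-credit) with a DeLong
structural-component Wald 95% CI, clipped to [0,1]; under perfect separation
the component variance is zero and the interval degenerates to (AUC, AUC)
with a warning.  Training AUC is computed on the SMOTE-balanced training set
(the data the model was fitted to); the "entire set" AUC uses only original
samples (whether the reference analysis re-used augmented data there is
unstated).  External validation applies a 0.5 probability threshold and
reports the confusion matrix, accuracy, precision, recall and F1, with
responder as the positive class throughout.  Validation samples are treated
independently even when one patient contributes two compartments.  Sample-id
bookkeeping asserts that no test or validation sample ever reaches SMOTE or
cross-validation.

Hub re-ranking of the selected genes runs the five centralities on the
induced subnetwork (degree exclusion disabled there — the rule is meant for
the full network) and flags genes that are both in at least four of five
top-k lists and response DEGs.

## Synthetic-data model

The generators are first-class, tested code and define the study conditions:

* **Discovery datasets** (default 3 datasets, 2000 genes, 30 cases / 30
  controls, log2 scale): per-gene baseline `N(7, 1.5)` shared across
  datasets, i.i.d. noise sd 0.5; 80 up / 40 down planted DEGs shifted by
  ±2 log2 units in cases; a latent hub-program activity `N(0,1)` in controls
  and `N(2,1)` in cases additively drives 30 up- and 10 down-hub genes with
  unit loading.  Hub genes are disjoint from the ordinary DEG lists so the
  two programs are separately checkable.
* **Panel cohorts** (default 5 datasets of 120 samples, 520 panel genes in 8
  blocks, 40 signature genes, 300 background genes): each dataset draws the
  latent activity per sample; signature genes load on it so the signature's
  ssGSEA score is a faithful proxy; a gene in block `b` of dataset `d` is
  `rho_b * atten_d * a + sqrt(1 - rho^2) * noise`.  Block correlations
  default to eight values evenly spaced on [0.8, -0.8] (two near zero,
  mirroring the weakly-correlated clusters seen in practice); attenuation is
  1.0 for the three tissue datasets and 0.75 for the two blood datasets, so
  block profiles differ by compartment instead of being collinear — with
  collinear profiles the WSS elbow would carry no information about the block
  count.  Uneven correlation spacing is still available as an argument and is
  exercised in the recovery tests.
* **Response cohorts** (default 200 patients, 2.76:1 responders to
  non-responders): the same block structure; labels follow a logistic model
  whose non-zero coefficients (scale 2 on standardized features) live on five
  genes of block 6 only; four of five coefficients are oriented so the genes
  are up-regulated in non-responders.  The class ratio is tuned by bisection
  on the intercept, not by subsampling.  A validation cohort reuses the same
  coefficients with a fresh draw.
* **Networks**: Erdős–Rényi background (p = 0.02, 200 nodes) with planted
  near-cliques on disjoint node sets.

What the generators deliberately do not model: probe/batch effects,
platform-specific noise, correlated null genes, and patient-level covariates.
Passing tests therefore demonstrate that each algorithm recovers the
structure it assumes, at realistic sizes and noise — not that the biological
conclusions of any particular cohort transfer.

## Problem sizes and numerical choices

The test and acceptance runs use the default generator sizes above; the
permutation null runs at 1000 sets (200 for the repeated-calibration check),
EPC at 100 trials in tests, K-means with 25 restarts, the LASSO path at 30
lambdas with 10-fold CV.  Probabilities are clipped at 1e-10 for deviance;
WSS monotonicity is checked with a 1e-6 relative tolerance; the k-means
random state and every other stochastic step derive from one master seed via
spawned seed sequences, and all pipeline outputs are plain text whose SHA-256
digests reproduce exactly under a fixed config.

## Known limitations

* The moderated model supports only two-group contrasts; no covariates,
  duplicate-correlation or array weights.
* EPC's percolation scheme and the MCODE parameter values are reconstructions
  of tools whose publications do not fully specify them.
* The elbow rule inherits the ambiguity of any curvature-based criterion on
  noisy WSS curves; the fixed k = 8 default sidesteps it.
* Cross-platform projection (microarray signature onto a targeted panel) is
  emulated by a shared latent factor; real platform transfer involves probe
  effects the generator does not model.
* The per-cluster AUCs are not nested-CV estimates; the held-out split is
  single, so test AUCs carry the variance of a ~40-sample evaluation.
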