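# Methods

cardiomap implements, as a tested library, a single-cell analysis stack for
characterizing hiPSC-derived endothelial cells against a labeled fetal
heart reference atlas: QC and normalization, mutual-nearest-neighbor (MNN)
batch integration, shared-nearest-neighbor (SNN) Louvain clustering,
diffusion pseudotime, negative-binomial (NB) GLM differential expression,
confidence-gated k-NN cell-type transfer, Jaccard comparison of marker
sets, and a combined bulk/pseudobulk PCA.  All guarantees are demonstrated
on synthetic data with complete ground truth; the generator is first-class
code, not a fixture.

## The synthetic-data generator

Counts are negative binomial with mean `mu` and dispersion `phi`
(`Var = mu + phi mu^2`), drawn via the gamma–Poisson mixture.  A dataset is
assembled from populations; population `p` has

    mu_gp = b_g * baseline_mean_p * 2^{log2fc_p * 1[g in markers_p]}

where `b_g` are per-gene baseline factors drawn log-normal(0, 0.5^2).  The
baseline factors give gene means the orders-of-magnitude spread real
transcriptomes have; without them every gene sits at one of two means and
the CV^2-versus-mean trend underlying HVG selection is degenerate (any
two-parameter trend interpolates two mass points exactly, erasing all
marker signal).  A query and its reference atlas share one draw of `b_g`
(the `gene_baseline` argument) because they describe the same genes.
Setting `gene_mean_sd=0` recovers a flat baseline.

On top of the population means, the query generator applies:

- **Library size** — a per-cell multiplicative factor, log-normal(0, 0.25^2)
  (`library_sd`).  This is what size-factor estimation has to undo.  Note
  that with library variation the marginal count variance exceeds
  `mu + phi mu^2`; moment-recovery checks therefore run at `library_sd=0`.
- **Batch effects** — gene-wise multiplicative factors `2^N(0, batch_sd^2)`
  shared by all cells of a replicate: the simplest structure an MNN-style
  correction should remove exactly.
- **Cell cycle** — a fixed fraction of cells (exactly
  `floor(cycle_fraction * n)`) gets an additive `cycle_log2_shift` on the
  log2-mean of designated non-marker genes and is labeled G2/M.  Additivity
  on the log scale makes linear regression removal exactly correct, giving a
  clean closed loop for the regression stage.
- **Contaminant** — an optional small population with its own
  (pluripotency-like) marker program, spread evenly over replicates.

The trajectory generator places cells evenly on a latent `t in [0,1]`;
program genes interpolate log-linearly (hence monotonically) between two
extreme states, half rising and half falling, remaining genes are
stationary noise.

What the generator does **not** emulate: gene–gene correlation beyond the
population/batch/cycle programs, doublets, ambient RNA, and zero inflation
beyond the NB.  Passing tests therefore demonstrate correctness of the
algorithms under the model the methods themselves assume, not robustness to
every artifact of real droplet data.

## Preprocessing

- **Cell filter**: keep cells detecting at least `min_genes` genes
  (count > 0).  **Gene filter**: keep genes with >= 2 cells at count >= 2,
  i.e. drop genes whose expression never rises above 1 in more than one
  cell; both thresholds are arguments.
- **Size factors**: pooling/deconvolution.  Cells are ordered by library
  size around a ring, alternating low/high so pools are balanced; for every
  window of sizes {21, 41, 61} the pooled profile is compared with the
  average-cell reference by a median ratio, giving one linear equation
  `sum_{j in pool} s_j = ratio`.  The stacked system plus one scale-anchor
  row is solved by non-negative least squares and rescaled to mean 1.
  Degenerate systems fall back to library-sum factors with a warning.  The
  median across genes is what buys robustness to composition effects; it
  costs ~25% efficiency relative to the library sum in the composition-free
  case.
- **Normalization**: `log2(1 + count / s_j)` exactly.
- **HVGs**: per replicate, fit `CV^2 ~ a + b/mu` on de-logged normalized
  counts by iteratively reweighted (Huber, c=1.345) least squares; the
  variability statistic is observed minus fitted CV^2, averaged across
  replicates (min/max available), with exclusion lists (ribosomal,
  mitochondrial, stress, proliferation, cycle genes — supplied as plain
  gene-id sets) removed before ranking.  Top `ceil(fraction * eligible)`
  genes are returned; `fraction` defaults to 0.05.  The lstsq-based fit
  degrades gracefully to a robust location fit if all means coincide.
- **Cell-cycle score**: fraction of (hi, lo) marker pairs with
  `expr(hi) > expr(lo)` (ties 0.5); G2/M above 0.2 by default.  This is a
  deliberate simplification of trained marker-pair classifiers: the pair
  list is an input, and the synthetic generator provides ground-truth pairs
  (each cycle gene against a quiet gene whose baseline sits at the
  geometric midpoint of the cycle gene's off/on means, so the comparison
  flips with phase).  Whether a trained classifier's score is numerically
  comparable at the same 0.2 threshold is an open question; the threshold
  is a parameter for that reason.
- **Covariate regression**: per-gene OLS on the binary phase call; residuals
  plus the gene grand mean, leaving residuals exactly orthogonal to the
  covariate.

## Integration and clustering

Batches are cosine-normalized, jointly embedded by exact SVD-based PCA
(d = 30 default; deterministic sign: largest-|loading| positive), and merged
sequentially in input order.  For each incoming batch, mutual k-NN pairs
(k = 20) against the running reference define pair vectors
(reference − incoming); each incoming cell moves by a Gaussian-weighted
average of pair vectors.  Two choices matter and were made deliberately:

1. **Kernel anchors are pair midpoints.**  For batches that are (shifted)
   copies of one another, mutual pairs come in twins (r, i)/(i, r) sharing a
   midpoint; with midpoint anchors their noise components cancel exactly,
   so identical batches receive exactly zero correction and a pure shift is
   recovered exactly.  Anchoring at incoming-side cells leaves an O(local
   spacing) residual in both cases.
2. **The pair-find/correct step is iterated (3x by default).**  Pair
   selection is biased along any remaining shift; the bias shrinks with the
   shift, so iteration contracts the residual geometrically (~77% offset
   removal in one pass, >= 95% after three on the standard scenario).

Bandwidth is `bandwidth_mult x median pair distance` (default 1.0); cells
beyond kernel support fall back to the mean pair vector.

The SNN graph connects cells whose self-inclusive k-NN sets intersect,
weighted by Jaccard overlap of those sets (rank-free); candidate pairs are
enumerated through a reverse membership index so sharing a neighbor
suffices even when the two cells never co-occur in one set.  Louvain
clustering runs on this weighted graph (networkx, seeded), labels relabeled
by descending size.  Cluster exclusion flags (reported, never silently
applied): `replicate-imbalance` when one replicate holds > 0.9 of a cluster,
`too-small` below 10 cells, and `pluripotency` when a cluster's mean
expression over a supplied pluripotency gene set exceeds the mean + 2 SD of
the *other* clusters' means (SD floored at 10% of the overall scale).  The
leave-one-out form is essential: including the candidate caps the maximum
z-score at `(n-1)/sqrt(n)`, which is below 2 for up to five clusters — the
regime this analysis actually operates in.

## Trajectory

The diffusion kernel is `K_ij = exp(-d_ij^2 / (sigma_i sigma_j))` on a
tie-inclusive k-NN graph (k = 20; all points within the k-th neighbor
distance are neighbors, so duplicate cells get identical rows), with
per-cell adaptive bandwidth `sigma_i` = distance to the ceil(k/2)-th
neighbor.  The kernel is max-symmetrized, row-normalized through the
symmetric conjugate `D^{-1/2} K D^{-1/2}`, and eigendecomposed exactly
(dense; the package operates at 10^2–10^3 cells).  Diffusion components are
the unit-normalized non-trivial eigenvectors scaled by their eigenvalues.
Pseudotime from a root cell is the closed form

    dpt(i) = || (lambda/(1-lambda)) * (psi(i) - psi(root)) ||

over retained components, equivalent to accumulating random-walk
transitions over the retained spectrum and exactly reproducible.
Components at eigenvalue 1 (disconnected graphs) are dropped with a
warning.  Root selection is the caller's: a cell id, or the extreme of the
first diffusion component via the `select_root` helper.  Cluster-level
connectivity is the observed/expected inter-cluster edge ratio
(`e_obs / E_total * C(n,2) / (n_a n_b)`), scaled by its maximum and clipped
to [0, 1].

## Differential expression

Per gene, `log mu = X beta` with NB variance at fixed gene-wise dispersion,
fitted by IRLS (convergence `max |dbeta| < 1e-8`, 100 iterations, linear
predictor clipped at +/-30).  Predictors: cluster and replicate (treatment
coding) and sequencing depth.  Depth defaults to log total counts as a free
covariate — the log link makes log-depth the natural scale — with raw-scale
and offset modes available; with one-sided DE the depth covariate absorbs
part of the effect (a property of the model, not a bug), so effect-recovery
simulations use balanced up/down marker blocks.  Dispersion is a
method-of-moments estimate from Poisson-fit residuals,
`phi = sum((y-mu)^2 - mu)/mu^2 / (n - p)`, shrunk 30% toward the median and
floored at 1e-8.  Contrasts are tested by a likelihood-ratio test: the null
model is the design projected onto the null space of the contrast, refitted
per gene; p-values are chi-square(1) and BH-adjusted (statsmodels).
Cluster-vs-rest markers use the contrast `beta_target - mean(beta_others)`;
replicate coefficients cancel in the additive model.  DEG-set comparisons
apply `p_adj < p_cut` and `|FC| > fc_cut` and exact set algebra.

## Reference mapping and label transfer

The feature space is the reference's top 10% HVGs restricted to genes
shared with the query.  Step 1 MNN-merges the query replicates; step 2 maps
the reference onto the combined query (the reference moves), all within one
joint cosine/PCA space (d = 30, k = 100).  Each query cell then takes the
modal type among its k = 100 nearest reference cells; confidence is the
modal vote share; `mean_nn_distance` is the mean distance to those k
neighbors (a strict 1-NN variant of the distance gate would be a trivial
change, the mean is the default).  A cell is UNASSIGNED when the mean
distance exceeds the gate, the vote share is below 0.5, or its query
cluster has under 10 cells.  The distance gate accepts either an absolute
value (meaningful only within one embedding's scale) or
`"quantile:q"` — the q-th percentile (default 99) of reference-internal
mean k-NN distances — because an absolute threshold is meaningless in an
embedding with a different scale.  Vote ties break by smaller mean distance
to the tied type's voters, then lexicographically.

Marker sets for Jaccard comparison take genes with `p_adj < 0.05`, restrict
to `log2fc > 0` (a marker is an upregulated gene — at atlas scale the
top-478 slice of a descending ranking makes this implicit; on small
universes it must be explicit), rank by log2fc descending and keep the
first 478 (tie-break by gene id).  Jaccard is `|A∩B|/|A∪B|`, 0 for two
empty sets (with a warning).  Pseudobulks are exact integer per-gene sums
over a cell subset.  The combined PCA log2(1+x)-transforms bulk +
pseudobulk totals, restricts to a marker panel, standardizes gene-wise
across samples (zero-variance genes dropped with a warning) and applies the
same deterministic-sign PCA.

## Pipeline, configuration, determinism

`run_pipeline` chains simulate → preprocess → integrate → cluster →
trajectory → differential expression → transfer, writing every artifact
(Matrix Market + TSV ids, CSV tables with 17-significant-digit floats) under
one output directory, with one structured log line per stage.  The YAML
config is strictly validated (unknown keys rejected; missing blocks named);
every stochastic stage draws a seed derived from the single global seed,
and the manifest records paths relative to the output directory, so a fixed
seed yields byte-identical artifact trees — verified by hashing two runs.
The `cardiomap` CLI exposes simulate, preprocess, cluster, trajectory, de,
jaccard and run; the integration, transfer and combined-PCA stages are
driven through `run` or the library API, whose inputs are multi-object.

## Default problem sizes

Tests and the acceptance script run at desk scale: 2 replicates of 80–150
cells per population, 200–1,500 genes, references of 240–1,500 cells —
sizes at which every linear-algebra step is exact and dense and a full
pipeline run takes seconds.  All operations are O(n^2) memory at worst
(distance matrices), which is the intended regime; nothing in the package
assumes sparsity.

## Known limitations

- The NB dispersion estimator is a simple moment/shrinkage scheme, adequate
  for calibration at these sample sizes but not numerically comparable to
  tagwise empirical-Bayes estimators.
- MNN correction assumes batches share at least one population; it raises
  rather than guessing when no mutual pairs exist.
- The pair-voting cycle score needs informative, reasonably expressed
  marker pairs; with weakly expressed pairs the score's noise floor rises
  toward 0.5.
- Library-size variation is indistinguishable from overdispersion unless
  depth is modeled; the DE design includes depth by default for exactly
  this reason.
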