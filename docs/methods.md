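# Methods

This note documents the models, the synthetic-data generator, and the
numerical and statistical choices behind `tissuegraph`.

## Problem setting

A cohort consists of multiplexed-imaging tissue samples ("images"): per-cell
2-D coordinates in fixed pixel-equivalent units, a discrete cell type with an
immune/non-immune binarization, a marker-expression vector, a per-image
categorical phenotype, and optionally right-censored survival for the
patient. Multiple images come from one patient, so all data splits are
grouped by patient. The task is graph-level: predict the phenotype of an
image, then ask *which* representation of the image the prediction needs —
its mean expression (bulk), its unordered cells (single-cell), its density
structure (graph statistics), or the full spatial graph.

## Spatial graphs

An image is represented by a binary symmetric adjacency with an edge between
cells strictly closer than a radius `r` (no self-loops, no edge weights).
Radii are taken from a hyperparameter grid rather than auto-tuned; the
`mean_degree_table` helper reports mean node degree as a function of `r` so a
sensible range can be chosen per cohort (for the default simulated cohorts,
`r = 50` at ~800 cells per 1000x1000 field gives mean degree ~6). The density
arm uses the normalized 16-bin degree histogram (degrees 0-14 plus an
overflow bin) or the bare graph skeleton with a constant scalar node feature,
which lets the same GNN code run the "structure without features" arm.

kNN graphs (used by spectral clustering and the expression-correlation
variant) symmetrize the union of directed k-nearest-neighbor lists; distance
ties are broken toward the lower node index so that the graph is a pure
function of the coordinates.

## Models

All neural models are built on a small reverse-mode automatic-differentiation
core over float64 NumPy arrays with sparse-matrix message passing
(`tissuegraph.nn`). Float64 keeps central-finite-difference checks of every
gradient hook below 1e-4 relative error, which the interpretation outputs
(saliency, filter gradients) rely on. Shared conventions: leaky-ReLU with
negative slope 0.1; mean pooling over nodes; a dense "graph embedding" stack
from the pooled representation to the output; fan-in-scaled uniform
initialization, seeded.

- **Bulk**: per-image mean marker vector or cell-type frequency vector into
  an MLP, random forest, or logistic regression.
- **Multi-instance (MI)**: a per-node dense stack, permutation-invariant
  pooling (mean/max/sum), then the graph stack.
- **GCN**: `H' = phi(D^-1/2 A D^-1/2 H W)` on the raw adjacency; degree-0
  nodes have zero normalized rows, so isolated nodes emit and receive
  nothing. **GCN_SUM** replaces the normalized adjacency with `A` itself.
- **GIN**: `h_i' = MLP((1 - eps) h_i + sum_{j in N(i)} h_j)` with `eps`
  fixed at 0 by default; the internal MLP is two dense layers of the node
  width. The `(1 - eps)` sign convention is kept as given; with `eps = 0` it
  coincides with the canonical `(1 + eps)` form. The readout concatenates
  the node embeddings of all layers (including layer 0) and mean-pools;
  because mean pooling commutes with concatenation this is computed as the
  concatenation of per-layer pooled embeddings.
- **GAT** (dot-product attention): `alpha_ij = softmax_j(x_i^T W_Q W_K^T
  x_j)` over the neighbors of `i`, with the per-neighborhood maximum
  subtracted before exponentiation; messages are the attention-weighted sums
  of the *raw layer inputs* transformed by `W_V` (a switch allows feeding an
  embedded representation instead; by default GAT consumes raw view features
  so the attention interpretation stays in type space). Query/key embeddings
  are 4-dimensional. Isolated nodes get the `sigma(0)` output row and are
  flagged.
- **Self-supervision head**: spectral clusters (symmetric normalized
  Laplacian eigenvectors + seeded k-means) on the coordinate kNN graph
  (k = 10); each cluster's target is the cell-type frequency vector pooled
  over all cells of its *neighboring* clusters (clusters linked by at least
  one kNN edge; a cluster with no neighbors is excluded from the loss). Node
  embeddings are mean-pooled per cluster, passed through a single linear
  layer, scored by MSE, and added to the task loss with weight `lambda`.
- **Multi-task heads**: extra linear heads on the shared graph-stack output,
  each with its own task kind and loss weight.
- **Permutation control**: node feature rows are shuffled within each graph
  (adjacency and per-graph feature multiset exactly preserved).

### Losses

Categorical cross-entropy for classification, MSE for regression,
BCE-with-logits for proportion targets, and a right-censored squared error
for survival: events contribute `(t_hat - t)^2`, censored subjects
contribute `max(0, t - t_hat)^2` (no penalty for predicting beyond the
censoring time), each part averaged over its own subjects. The hinge form is
the minimal reading of a "right-censored MSE" and is isolated behind the
loss interface.

### Training

Adam with optional L2 weight decay, reduce-on-plateau learning-rate
scheduling (factor 0.5, patience 10 on the monitored loss), mini-batches of
whole graphs (default 16; the experiment drivers use full-batch training,
which is faster for these graph sizes because every graph in a batch is
stacked into one block-diagonal sparse adjacency). Early stopping monitors
the validation loss with patience 20 (max 500 epochs) and restores the best
epoch; the fixed-epoch mode (default 100) is used when no validation fold
exists. Non-finite losses abort with a diagnostic.

## Evaluation

Splits are drawn on patients: 3 random test splits crossed with 3 validation
splits (train/validation/test fractions 0.8/0.1/0.1), or a train/test-only
mode (0.8/0.2) for small cohorts in which the three inner cells are training
replicates and selection uses the training loss. Every fold must contain
every class (re-drawn up to a retry cap). The same plan is shared by all
arms of an ablation.

AUPR follows the step-wise definition `sum_i (R_i - R_{i-1}) P_i` with
thresholds at the distinct predicted scores in descending order and `R_0 =
0`; multi-class tasks use the unweighted (macro) mean of one-vs-rest values;
binary tasks score the positive class. The implementation is validated to
1e-9 against an independent loop-based reference and against
scikit-learn's `average_precision_score`. Hyperparameters are selected per
outer split by the lowest mean validation (or training) loss; test AUPR is
reported for the nine (outer x inner) winning models. Arms are compared by
an unpaired two-sided t-test on the two 9-vectors (identical degenerate
vectors give p = 1); the mean positive-class prevalence across the nine
test cells is the random-predictor baseline.

**Statistical caveat.** The nine nested-CV values share three test folds, so
they are not independent samples and the t-test is approximate, as in the
original design. Two regimes matter in practice. For neural arms, per-cell
random initialization injects independent ranking noise, the shared
fold-composition noise cancels between arms evaluated on the same folds, and
the test is calibrated to conservative (0/20 null rejections in the
calibration experiment). For deterministic arms (logistic regression,
random forest), the three inner models of an outer split make nearly
identical predictions, the nine values collapse to about three effective
draws, and the test becomes anticonservative under the null. The comparison
is reported as defined (unadjusted; an optional Holm flag exists) and the
calibration experiment uses neural arms. A second finite-sample effect is
that the AUPR of a signal-free ranking on a small test fold is biased above
prevalence (about +0.05 at 32 images); null arms are therefore judged
against the prevalence baseline with a 0.1 band at the fold sizes used.

## The synthetic cohort generator

The generator emulates the statistical shape of multiplexed-imaging cohorts:
tens of patients, a few images per patient, 1e2-1e4 cells per image in a
square field (default side 1000, unit-free pixel equivalents), six cell
types (tumor, fibroblast, stroma/endothelial; macrophage, T cell, B cell
mapped to immune), archetypal marker panels (each type highly expresses two
dedicated markers; Gaussian per-type dispersion plus background noise,
clamped at zero). Class labels are assigned to patients by exact quota, and
the label is encoded through exactly one channel:

- **composition**: immune fraction interpolates between the class targets
  with `strength`.
- **density**: the per-image expected cell count is `intensity x area` per
  class (Poisson counts).
- **arrangement**: both classes share one uniform point pattern and the same
  immune fraction; the aggregated class assigns the immune *label* with
  probability proportional to a Gaussian-mixture kernel around a few
  aggregate centers (plus a uniform background component), the diffuse class
  by uniform thinning. Keeping positions identical in law across classes is
  deliberate: the point process, adjacency, degree histogram and composition
  carry no signal, so spatial arrangement of the immune label is the *only*
  channel — the permuted-features control and all density arms must sit at
  the prevalence baseline. (An alternative design that generates the
  aggregated class with a Thomas-type clustered point process makes the
  adjacency itself class-informative and was rejected for this reason.)
  Aggregate membership (within two kernel sds of a center) is recorded as
  generator ground truth for the saliency analyses.
- **interaction**: in one class, the `strength` fraction of non-target cells
  nearest to target-type cells is relabeled to the source type; the other
  classes relabel the same number of uniformly chosen cells, so type
  composition stays matched and only the spatial association is planted.
- **ordinal_grade**: a per-patient latent severity `s ~ U(0, 1)` (with a
  small within-patient jitter, default sd 0.05) sets the grade by tertile
  thresholds and linearly interpolates the composition/arrangement
  parameters; survival is `T ~ Exp(rate = a * exp(b * s))` with independent
  `U(0, c)` censoring. Defaults `a = 0.1`, `b = 3.0`, `c = 15` give roughly
  25-30% censoring and an oracle severity-vs-survival concordance of about
  0.70; a weaker effect (`b = 1.5`) caps the oracle concordance near 0.62,
  leaving no headroom to detect prognostic signal in learned embeddings,
  which is why the stronger default was chosen.

At `strength = 0` every channel reduces to identical class-conditional laws;
this is enforced by construction and checked by permutation-calibration
tests. What the generator does *not* emulate: segmentation artifacts,
marker spillover, spatially varying cell morphology, batch effects, or
realistic marker covariance structure. Passing the synthetic experiments
therefore shows that the pipeline recovers the signal classes it claims to
recover under clean conditions, not that any given real cohort contains such
signals.

## Interpretation analyses

- **Embeddings**: activations after global node pooling, one row per image,
  quantile-normalized per feature (rank-based, uniform on (0, 1]) and
  decomposed by centered PCA. PC signs are fixed by making the
  largest-magnitude loading positive; constant features are dropped with a
  warning. For survival scoring, PC1 is averaged per patient and oriented by
  the observable grade ordering (grade-3 mean above grade-1 mean) before
  computing the concordance index.
- **Concordance**: comparable pairs are those whose earlier time is an
  event; a pair is concordant when the earlier subject has the larger
  predictor (risk convention); predictor ties credit 0.5; equal times are
  not comparable. Validated exactly against an O(n^2) pair scan and against
  lifelines' convention.
- **Attention-type matrix**: with one-hot type inputs the pre-softmax score
  of query type q against key type k is `(W_Q W_K^T)[q, k]`; scores are
  max-subtracted per key and exponentiated, so each key column has maximum
  1 and the matrix is invariant to per-key score shifts.
- **Filter context**: the first-layer value matrix `W_V` (rows indexed by
  the neighbor type) scaled by the attention row of the queried cell type,
  set into context by the per-class average gradients of the outputs with
  respect to the first-layer filter activations. The pair-relevance ranking
  used in the experiments multiplies the attention score of a (query, key)
  pair by `sum_f |W_V[key, f]| * |g1_f - g0_f|`, the key type's weight on
  class-discriminative filters.
- **Saliency**: gradient of `logit_1 - logit_0` with respect to each node's
  input row, reduced to the gradient on the cell's active indicator for
  one-hot/binary spaces (L2 norm signed by the row-gradient sum for
  molecular inputs). The logit difference makes the sign convention well
  defined: positive points to class 1. Stratification uses degree bins of
  width 5 (0-30 plus overflow) and immune-fraction bins of width 0.2 by
  default. In the arrangement experiments the informative contrast is
  between immune cells inside planted aggregates and immune background
  cells at matched degree: the trained models treat scattered immune mass
  as evidence *against* the aggregated class, so background immune cells
  carry negative saliency while aggregate members are positive.
- **Neighbor composition**: per image, the type frequencies among
  radius-graph neighbors of a query type (normalized per image), averaged
  per class; the reported vector is the class difference. Images without
  the query type or without neighbors are excluded with a warning.

## Experiment sizes

The bundled experiments (acceptance tests and `scripts/acceptance.py`) use
cohorts of 20-100 patients with 3-4 images each and 100-800 cells per
image, and single-point hyperparameter grids with the defaults above; these
sizes are large enough for every planted effect to be recovered with a wide
margin while keeping a full run in minutes on one CPU. The full grids of
the original design (learning rate, weight decay, radius, cluster counts,
depths and widths) remain available through the `grid` argument of the
ablation driver.

## Known limitations

- The autodiff core implements exactly the operations the models need; it
  is not a general-purpose framework (no broadcasting beyond NumPy rules,
  no higher-order gradients).
- Spectral clustering uses a dense eigendecomposition below 200 nodes and a
  shift-invert Lanczos solver above; very large graphs (>1e5 nodes) will be
  slow.
- The nested-CV t-test caveat above applies to any use of `compare()` on
  deterministic models.
- Weighted (distance-valued) adjacencies are not implemented; the binary
  thresholded graph is the only spatial representation.
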