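# Methods

## Problem and model

Given a binary disease–miRNA association matrix `A` (nd×nm), a partially
observed miRNA functional-similarity matrix FS, and per-disease ontology
ancestor DAGs, the package scores every unverified pair by completing `A`
as `Z = Sd·W·H·Sm` with nonnegative factors, where `Sd` and `Sm` are dense
integrated similarity matrices acting as disease and miRNA feature maps.
The factors minimize the generalized KL divergence

    D(A‖Z) = Σ_ij [ A_ij ln(A_ij/Z_ij) − A_ij + Z_ij ],  W, H ≥ 0,

by alternating multiplicative updates. KL loss on a binary target treats
`A` as counts of observed links; zeros are soft — they contribute only the
linear term `Z_ij`, which is what makes the method usable without negative
samples.

## Similarity construction

**Semantic similarity (diseases).** Each disease's DAG is its ancestor
closure T(D) with parent→child edges. Model 1 assigns the disease's own
node contribution 1 and each ancestor `Δ · max(children's contributions)`,
i.e. `Δ^(shortest hop distance)` under the max rule; model 2 weights a node
by `−ln(fraction of DAGs containing it)`, so ubiquitous terms contribute
nothing and rare terms a lot. A pair's score under either model is the sum
of both diseases' contributions over shared nodes divided by the sum of
their semantic values, which lies in [0,1]; SS averages the two models.
Both models use the diseases present in the DAG table as the reference
population for model-2 frequencies. The logarithm is natural; any base
would only rescale numerator and denominator of the model-2 ratio jointly
for shared terms, but we fix one for reproducibility. Pairs of diseases
whose model-2 semantic values both vanish (every node ubiquitous, e.g. a
single-disease table) are scored 0 under model 2 rather than 0/0.

**q-kernel similarity (both sides).** Interaction profiles (rows/columns of
`A`) are compared with
`H_q(x,y) = (1/(1−q))(q^(−1/c) − q^(−1/√(‖x−y‖²+c²)))`, the q-analog of the
inverse multiquadric kernel: zero iff `x=y`, strictly increasing in the
distance, bounded by `(q^(−1/c)−1)/(1−q)`. Distances are min–max scaled
over **off-diagonal pairs only** (so the forced unit diagonal cannot skew
the range) and flipped into similarities. If every pairwise distance is
identical — which happens when a degenerate training fold zeroes all
profiles — the similarity is all ones with a logged warning rather than an
error, so cross-validation folds always run.

**Integration.** Where FS/SS is observed, `S = ω·known + (1−ω)·kernel`;
elsewhere the kernel value stands alone. With the trained default
`ω = 0.01` the external similarity contributes only 1%; this weighting is
deliberately preserved as published. The output is symmetric, dense, in
[0,1], unit diagonal — exactly the nonnegative inputs the multiplicative
updates require.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `c` | 0.1 | kernel width offset, (0,1]; smaller c sharpens the kernel |
| `q` | 0.6 | q-deformation, (0,1); q→1 degenerates (excluded) |
| `ω` | 0.01 | weight on externally known similarity in the blend |
| `Δ` | 0.5 | per-edge semantic decay, (0,1] |
| `r` | `"auto"` | factor rank; auto = PCA of Sm at 95% cumulative variance |
| `max_iter` | 100 | multiplicative-update sweeps |
| `tol` | 1e-8 | relative objective change for early stop (0 disables) |
| `ε` | 1e-12 | floor on elementwise denominators and log arguments |

`c`, `q`, `ω` and the 100-sweep cap are the published trained values. Δ is
the convention of the functional-similarity lineage this model family
builds on. The PCA rank selection is run on `Sm` (configurable); at the
reference data scale the published choice is k=114, which requires the
external databases and is documented here as a constant, not derived.

## Numerical choices

* **Initialization.** W, H ~ uniform(0,1) from the run seed, jointly
  rescaled so the initial reconstruction has mean `max(mean(A), 1e-3)`.
  Starting on the data's scale keeps the first KL log terms small; the
  floor protects near-empty training folds.
* **Monotone descent.** The updates are the exact multiplicative rules for
  the linear nonnegative parameterization `Z = Sd W H Sm`; the objective is
  non-increasing (verified to 1e-9 relative over randomized instances) and
  zeros in the factors are absorbing.
* **Guards.** Elementwise divisions and the KL log floor at ε=1e-12. Terms
  with `A_ij = 0` contribute exactly `Z_ij` (0·ln 0 := 0).
* **Early stopping** at relative objective change < 1e-8 is an addition to
  the fixed 100-sweep budget; set `tol=0` for strict fixed-iteration runs.
* **Ties.** AUC uses midranks; candidate ranking uses stable sort, so equal
  scores keep input order in written top-k lists.

## Cross-validation

LOOCV hides each verified pair in turn; k-fold partitions the positives
uniformly per repetition (seeded; empty folds trigger a logged
repartition). The kernel similarities QM/QD are **rebuilt from each
training matrix** by default — they derive from `A`, so reusing full-data
kernels leaks the held-out label (measurably inflating AUC; the leaky mode
is available for replication studies via `recompute_similarity=False`).
FS and SS are never rebuilt: they encode external knowledge independent of
`A`. Candidates are all pairs unknown in the full matrix, globally pooled.
The LOOCV global AUC is the mean over held-out pairs of each pair's midrank
AUC against the candidate pool; k-fold reports mean ± sample std (n−1)
over repetitions of the per-repetition fold-averaged AUC.

## Synthetic benchmark

The generator plants a rank-r latent matrix `L = U·V` (nonnegative uniform
factors), binarizes its top `density·nd·nm` entries into `A` (seeded jitter
breaks ties), derives FS as cosine similarity of latent columns masked to a
target coverage (default 20.58%, the completeness of the real functional-
similarity network), and grows a shared ancestor forest in which diseases
with similar latent weight attach to the same branch. Defaults — 20×30,
rank 2, density 0.1 — keep a full LOOCV (~60 refits) in seconds.

What passing tests show: the pipeline recovers planted low-rank structure
(LOOCV AUC ≥ 0.9 across seeds) and carries no leakage (shuffled-label AUC
≈ 0.5). What they do not show: performance on real catalogues, whose degree
distributions are heavy-tailed, whose DAGs are far deeper and re-convergent,
and whose functional similarity is not cosine-of-latent-factors. The
published reference-scale results (LOOCV AUC 0.9235, five-fold
0.9170 ± 0.0006) require the external databases and are documented, not
reproduced here.

## Known limitations

* KL loss is sensitive to noise and outliers in the association catalogue.
* Entities with no known associations get their similarity entirely from
  degenerate profiles; predictions for them are weak by construction.
* LOOCV at reference scale means thousands of refits; `max_folds`
  subsampling exists for smoke testing and is an approximation.
* One kernel family is implemented; the distance function is isolated in
  `qkernel_distance` as the single extension point for other q-kernels.
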