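# Methods

## Problem and model

`scanchor` clusters n cells measured in two matched modalities, an
scRNA-seq gene×cell count matrix and an scATAC-seq peak×cell matrix. Both
are treated as views `X_i ∈ R^{d_i×n}` of one latent partition; a third,
feature-merged view (RNA rows stacked on ATAC rows) is included by default
so that cross-modality covariation enters the shared factorization
directly (`use_merged_view` disables it).

Instead of an n×n cell graph, all structure is routed through m anchors
(m = `anchor_multiplier` × k, multiplier in {10, …, 60}, k the requested
cluster count). Three representations are learned:

1. **Specific anchor graphs** `Z_1, Z_2` (m×n, nonnegative, column sums 1):
   for each omic, `min_Z ‖X − Y Z‖² + ρ‖Z‖²` over the column simplex, with
   anchors `Y` seeded from k-means centroids of a random cell subsample
   (half the cells by default, never fewer than m) and optionally refit by
   regularized least squares.
2. **A shared anchor graph** `Z_s` with shared anchors `Y_s` (d×m,
   orthonormal columns), per-view orthonormal projections `W_i` (d_i×d) and
   simplex view weights `α`, minimizing
   `∑ α_i²‖X_i − W_i Y_s Z_s‖² + ‖Z_s‖²`.
3. **A high-order shared representation** `Z_s′`: columns of `Z_s` are node
   features of the cell kNN graph and are propagated through stacked
   multi-head masked-attention layers.

Completion and fusion: `Z_im1 = Z_s′ ⊙ Z_1`, `Z_im2 = Z_s′ ⊙ Z_2`,
`Z_final = θ Z_im1 + (1−θ) Z_im2`, followed by k-means over the columns of
`Z_final` (10 restarts, best inertia). The Hadamard completion assumes the
rows of `Z_s′` still index the same anchors as `Z_1`/`Z_2`; this assumption
drives two design choices below.

## Optimization

The shared objective is minimized by two interleaved phases.

**Closed-form phase** (every `validate_every` iterations): a cyclic pass
W → Z_s → Y_s → α in which every block is solved exactly:

- `W_i = U Vᵀ` from the thin SVD of `X_i Z_sᵀ Y_sᵀ` (orthogonal Procrustes;
  because `(W_i Y_s)ᵀ(W_i Y_s) = I`, the residual term is linear in `W_i`
  and the Procrustes maximizer is the exact block minimizer). A warning is
  raised when the target is rank deficient (maximizer not unique).
- `Z_s`: the objective is isotropic in `Z_s`, so the constrained minimizer
  is the Euclidean simplex projection, column-wise, of
  `∑ α_i² Y_sᵀ W_iᵀ X_i / (∑ α_i² + 1)`. The `+1` in the denominator
  carries the unit-weight `‖Z_s‖²` regularizer; dropping it
  (`include_regularizer=False`) reproduces the plain quadratic-form target
  but is then not an exact minimizer of the full objective and can break
  descent, so the regularized form is the default.
- `Y_s = U Vᵀ` from the thin SVD of `∑ α_i² W_iᵀ X_i Z_sᵀ`.
- `α_i ∝ 1/O_i` with `O_i = ‖X_i − W_i Y_s Z_s‖²` (exact minimizer of the
  weighted-residual term over the simplex, by Cauchy–Schwarz). Views with
  exactly zero residual split the weight uniformly — the formula's limit.

Since each block update is an exact minimization started from the previous
cycle's endpoint, the objective recorded once per cycle is non-increasing;
the run stops when its relative change falls below `tolerance` (1e-6) or
after `max_iterations` (1000).

**Gradient phase** (all other iterations): per-view two-layer graph
convolutional networks `Z_GCN^i = Â_i relu(Â_i H_i W′_1) W′_2` with
`Â = D′^{−1/2}(A+I)D′^{−1/2}`, trained by Adam (lr 0.01, weight decay 5e-3)
on the shared objective with `Z_s` tied to the aggregation
`Z_s = ∑ α_i Y_sᵀ Z_GCN^{iᵀ}` and all closed-form blocks frozen. Gradients
are derived in closed form (the orthonormality of `W_i Y_s` collapses
`∂L/∂Z_s` to `2[(∑α²+1)Z_s − ∑α² Y_sᵀW_iᵀX_i]`), so no autodiff framework
is needed. GCN input features are the per-view truncated-SVD reduction of
the view to d dimensions; the per-view graph is the cosine kNN graph over
cells. At each validation point the GCN's simplex-projected `Z_s` proposal
is adopted only if it does not increase the objective — this preserves the
cooperative GCN/closed-form design while keeping the per-cycle trace
monotone. The shared dimension defaults to d = m (the smallest d compatible
with `Y_sᵀY_s = I_m`).

The specific-graph Z-step (ridge solve, then column-wise simplex
projection) is not guaranteed to descend, because the projection of the
unconstrained ridge minimizer is not the constrained minimizer when
`YᵀY + ρI` is anisotropic; candidate columns are therefore accepted only
where they lower that column's objective, and the Y-refit is accepted only
if it lowers the total. This makes the recorded trace non-increasing by
construction.

## Attention stage

Defaults: 2 layers, 3 heads, every layer maps m → m so the output matches
the m×n shape the Hadamard completion needs. Attention logits use
LeakyReLU (slope 0.2) on `aᵀ[Wh_i ‖ Wh_j]`, softmax-normalized over each
neighborhood (kNN graph on `Z_s` columns plus self-loops, so no
neighborhood is empty); heads are averaged, with ELU between layers and a
linear final layer. Parameters are drawn once from the run seed and not
trained — no separate attention loss exists in this model, so the stack
acts as a fixed, reproducible high-order propagation operator. The shared
weight matrices
are initialized as identity plus 0.1× Glorot noise rather than pure noise:
an arbitrary dense map would scramble the anchor identity of the rows of
`Z_s′`, which the downstream entrywise products assume.

## Numerical choices

- **View scaling.** After normalization (RNA: per-cell library scaling to
  the median depth, then log1p; ATAC: TF-IDF with log1p of the 1e4-scaled
  product), the pipeline scales each view to unit mean per-cell energy
  (`rescale_views`). At the raw scale the unit-weight `‖Z‖²` regularizers
  are negligible against the reconstruction terms and the simplex
  projections return one-hot columns — hard anchor assignments whose
  columns are mutually equidistant and carry no between-anchor geometry,
  which destroys downstream k-means. Unit energy makes the two terms
  commensurate and the graphs soft.
- **Simplex projection** uses the exact sort-and-threshold algorithm,
  vectorized over columns; ties and all-negative inputs are handled by the
  thresholding itself.
- **kNN graphs**: cosine similarity, k = 15 by default (k is capped at
  n−1), union-symmetrized, zero diagonal, similarity ties broken by
  ascending cell index for determinism.
- **Degenerate inputs**: all-zero matrices are rejected before
  normalization; zero-residual views take the uniform-split α limit;
  rank-deficient Procrustes targets warn; the specific-graph Y-refit uses
  ridge ε = 1e-8 against singular `ZZᵀ`.
- **Determinism**: every stochastic component (subsampling, k-means,
  GCN/GAT initialization) derives from the single run seed; two runs with
  the same seed produce bitwise-identical graphs and labels.

## Synthetic data

The generator plants one latent partition shared by both views. RNA:
gene-wise baseline log-means ~ N(0.5, 1); each cluster's marker block
(genes split evenly across clusters) is shifted up by
`rna_mean_separation` (default 2.0, in units of the baseline SD); counts
are gamma–Poisson (negative binomial, variance μ + 0.3 μ²) with 30%
random dropout. ATAC: peaks split into per-cluster blocks, open with
probability 0.3 inside a cell's cluster block and 0.02 elsewhere. Defaults
are n = 300 cells, k = 3 clusters, 200 genes, 500 peaks. A
`moderate_overlap_spec` variant (separation 0.8, dispersion 0.6, open
rates 0.12/0.05, dropout 0.4) produces partially overlapping clusters for
ablation comparisons.

What this emulates — and what it does not: the generator reproduces
over-dispersion, dropout, near-binary sparsity and the dimensional
asymmetry between views, but not batch effects, doublets, peak–gene
regulatory linkage beyond the shared labels, library-size gradients, or
the long-tailed cluster-size distributions of real tissues. Passing
recovery tests therefore demonstrates the machinery is correct and
noise-robust in these regimes, not that real-data performance matches.

## Known limitations

- On synthetic data where both views carry the *same* partition, the
  shared graph alone can out-cluster the fused representation, because the
  specific graphs add redundant noise rather than complementary signal;
  the fusion stage earns its keep only when modalities disagree
  informatively. The stage-wise ablation check treats ordering violations
  as warnings for this reason.
- Dense n×n similarity matrices are formed during kNN construction;
  suitable up to tens of thousands of cells, not hundreds of thousands.
- The final clusterer is k-means with a known k; no automatic model
  selection.
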