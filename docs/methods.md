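# Methods

## Problem setting

A golden-standard PPI network `G = (V, E)` with `m = |V|` proteins is
represented by a binary symmetric adjacency matrix `A` with zero diagonal.
`E` is partitioned into a training edge set `E_tn` (the network `G_tn`,
kept over the full node set `V`) and a held-out test set `E_tt`.  The
training fraction is capped: exactly `floor(ratio_cap · |E|)` edges are
sampled uniformly without replacement under a seed.  Uniform edge sampling
is the simplest procedure that satisfies the intended properties — the
achieved ratio never exceeds the cap, and at small caps the training
network is extremely sparse and falls apart into many components, isolated
proteins included (they count as size-1 components in every census).  Other
subsampling schemes that respect the cap would serve equally; the choice is
documented rather than claimed canonical.

## Evolution neural network

Architecture: five fully connected layers of sizes `m, h1, h2, h3, m`,
sigmoid activation at every layer, inverted dropout on the input and hidden
activations during training only.  Each protein is one training example:
the input is the all-zero vector (default) or the one-hot row indicator,
the label is the protein's row of the training adjacency.  The loss is
binary cross-entropy, summed over output units and averaged over rows,
with probabilities clamped at `1e-7` to avoid `log 0`.  There is no
layer-wise pretraining.  Training uses Adam; the epoch loss is recomputed
on the full data with dropout disabled (this is the logged series and the
early-stopping signal), and training stops at `max_epochs` or when the
loss has improved by less than `loss_tolerance` for `patience` consecutive
epochs.  The evolved matrix `EA` is the forward pass with dropout off.

Defaults (all configurable): `h1 = h3 = max(16, ⌈m/2⌉)`,
`h2 = max(8, ⌈m/8⌉)` — a mirror-image bottleneck so the middle layer is a
"smaller ancient interactome"; dropout 0.2; learning rate 1e-3; 500
epochs; full batch for `m ≤ 1000`, else 256; patience 20; tolerance 1e-6.
A hidden layer as wide as the network is allowed but warns, since the
bottleneck interpretation no longer holds.

**Zero-input degeneracy.**  With literally identical all-zero inputs the
first-layer weights receive zero gradient and the network is a constant
predictor; the cross-entropy optimum of a constant predictor is the label
column means, so every row of `EA` is identical and converges to
`mean(A[:, j])` — essentially a smoothed degree profile.  This is the
formulation's literal behaviour and is kept as the default
(`input_mode="zeros"`); `input_mode="identity"` feeds one-hot rows and
yields row-distinct outputs for users who want a non-degenerate
reconstruction.  Both behaviours are asserted in the test suite.  Notably,
the degenerate mode is still informative: `EA' + EA` encodes a
degree-profile similarity that densifies the transition matrix (see next
section), and that alone is what lets diffusion reach across disconnected
components.

## Transition matrix and regularized Laplacian kernel

`T = sigmoid(EA' + EA + A)` is symmetric by construction; the diagonal is
not zeroed (it cancels out of `L = D − T` in any case, since `D` holds the
row sums of `T`).  Because `EA ∈ (0,1)` and `A ∈ {0,1}`, the sigmoid
argument lies in `(0, 3)` and every entry of `T` is inside `(0.5, 0.953)`:
`T` is dense by design.

Scores are `P = (I + αL)⁻¹` with `α = alpha_fraction / ρ(L)`,
`alpha_fraction ∈ (0, 1)` (default 0.5), which guarantees the convergence
bound `0 < α < ρ(L)⁻¹` of the equivalent Neumann series `Σ αᵏ(−L)ᵏ` for
any input.  `ρ(L)` is computed by power iteration with a deterministic
start vector, a Rayleigh-quotient residual tolerance of 1e-8 and a 10,000
iteration cap, falling back to a dense symmetric eigendecomposition
(`m ≤ 2000`) when the iteration stalls (e.g. a near-degenerate ±λ pair).
`P` is obtained by a symmetric positive-definite linear solve, not an
explicit inverse or truncated series; the series is retained in the tests
as an independent oracle.  `L` is positive semidefinite (weighted graph
Laplacian), so the solve cannot be singular for `α > 0`; `T` itself need
not be positive semidefinite and no such property is asserted.  The
degenerate case `L = 0` (no off-diagonal mass) returns the identity.

ADJ-RL, the baseline, is the identical kernel applied to the raw binary
training adjacency.  On a disconnected training network its score matrix
is block diagonal: cross-component pairs all score 0 and are unrankable,
which is the failure mode the evolved transition matrix removes.

## Kernel fusion (WOLP)

Feature kernels are symmetric matrices over the shared node order,
min-max normalised to `[0, 1]` (a constant kernel maps to all zeros —
the convention avoids division by zero and contributes nothing to
fusion).  Graph-topology kernels are computed from the training network
only, never from test edges: Jaccard neighbourhood overlap (diagonal 1
for nodes with neighbours, 0 for isolated nodes) and the degree-sum
shared-neighbour kernel.  Sequence (BLAST), co-expression and Pfam-domain
kernels are consumed as precomputed matrices with an ID header; loading
realigns them to the node order and rejects unknown or missing IDs and
asymmetries above 1e-6.

The fusion weights solve

minimise `‖W₀·G_tn + Σᵢ Wᵢ·Kᵢ − T‖²_F` subject to `W ≥ 0`,

as a nonnegative least-squares problem over the vectorised matrices
(`scipy.optimize.nnls`).  Nonnegativity is imposed because the weights
combine similarity kernels; no sum-to-one constraint is added (none is
required by the objective, and the equal-weight baseline `Wᵢ = 1/(n+1)`
is representable).  With the ENN transition matrix as the target this is
the ENNlp mode; equal weights give the EW baseline.  Planted-mixture
recovery is exact (to solver precision) whenever the stacked matrices are
linearly independent, which random kernels almost surely are.

## Evaluation

Positives are the test edges; candidate negatives are all unordered
non-self pairs absent from `E` entirely.  AUC is the rank-based
probability that a random positive outscores a random negative with ties
at half credit (equivalently the trapezoidal area under the ROC curve);
scores are read from the upper triangle of the symmetric `P`.  The
exhaustive negative set is the default up to 2000 nodes; above that a
seeded sample of `neg_ratio` negatives per positive is drawn and recorded.
Published AUC values for this family of methods depend on the (usually
unstated) negative-set convention, so absolute numbers are comparable only
within a fixed convention.

Repeated benchmarks re-split with seeds `base_seed + r`, run every
requested method on the same split, and report mean ± sample (n−1)
standard deviation per method.

The reconnection analysis ranks all candidate pairs (excluding training
edges) by score, descending, with deterministic lexicographic tie-breaks;
the top `floor(ρ·N)` pairs are the predicted positives `G_pp`, their
intersection with the test edges is `G_ptp`, and the curve reports the
number of connected components of `G_tn ∪ G_ptp` per ρ.  Supersets of
recovered edges can only merge components, so the curve is non-increasing,
from `components(G_tn)` at ρ → 0 to `components(G_tn ∪ G_tt)` at ρ = 1.

## Synthetic data

The generator grows a duplication–divergence graph: from a seed triangle,
each step duplicates a random node, retains each parent edge with
probability 0.4 and attaches duplicate to parent with probability 0.1
(both configurable), fully deterministic under a seed.  This mimics the
evolutionary process thought to shape real interactomes and reproduces
their right-skewed degree distributions (hubs emerge because high-degree
nodes are hit by duplications more often).  It does not emulate curation
bias, false-positive interactions, or the sheer size of real golden
standards (thousands of proteins); desk-scale runs use n = 300.  Passing
benchmarks on these networks therefore demonstrates correct mechanics and
the qualitative ENN-RL > ADJ-RL ordering under extreme sparsity — not the
absolute AUC levels reported on curated yeast or human data.

Edge-list files carry edges only; proteins that end up isolated are not
representable in that format, so the `split` command writes a `nodes.tsv`
sidecar with the full node universe and downstream commands restore it.

## Problem sizes and determinism

Default verification runs use networks up to n = 500, transition matrices
up to m = 30 for closed-form checks, and 5 seeded replicates for the
benchmark — sizes at which every quantity is recomputable in seconds while
still exhibiting the disconnected-training regime the method targets.
Every stochastic step (splits, weight initialisation, dropout, negative
sampling, the generator) is driven by an explicit integer seed through
numpy's `default_rng`; identical seeds give bitwise-identical training
logs, splits and score matrices.

## Known limitations

- The zero-input mode's evolved matrix is rank-one (identical rows); all
  pairwise signal beyond the adjacency enters through the degree-profile
  term.  `identity` mode lifts this but is a documented departure from the
  literal zero-prior-knowledge formulation.
- Dense `O(m²)`–`O(m³)` linear algebra throughout; the implementation
  targets networks up to roughly 10⁴ nodes and provides no sparse or
  approximate solvers.
- The split procedure is a documented surrogate (uniform edge sampling at
  the cap); no claim is made that it matches any particular published
  division step beyond its stated invariants.
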