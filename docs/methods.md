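# Methods

## Problem and model

Given experimentally validated SM–miRNA associations plus auxiliary
miRNA–disease and SM–disease associations and SM/miRNA/disease similarity
data, the package predicts unobserved SM–miRNA associations. The working
assumption is that association structure is low-rank: compounds and
miRNAs that share latent biological factors are both co-associated and
mutually similar, so topology of the joint heterogeneous network is
informative about missing links. All six sub-networks are treated as
undirected; association edges carry weight 1 and similarity edges carry
their similarity value.

## Disease semantic similarity

A disease's MeSH-style tree numbers induce an ancestor DAG (union over
tree numbers; edges parent → child). Contributions decay geometrically
with the shortest directed distance to the disease,
`D_d(t) = Δ^dist(t,d)` — equivalently the recursive
`D_d(t) = max_{t' ∈ children(t)} Δ·D_d(t')` with `D_d(d) = 1`, where the
max selects the shortest of multiple paths. `DV(d) = Σ_t D_d(t)`, and the
similarity of two diseases is the sum of their contributions over shared
DAG nodes divided by `DV(d_i) + DV(d_j)`. Δ defaults to 0.5 and is fixed
per run; comparing profiles computed with different Δ is an error.

Node identity matters for the shared-node intersection: a tree position
that is itself a named disease is labelled with that disease id, so a
parent disease is recognised inside its descendants' DAGs; unnamed
positions stay anonymous (keyed by tree-number prefix) and only named
diseases appear in the output matrix. Two diseases claiming the same full
tree number would make that labelling ambiguous and are rejected.
Diseases absent from the tree table simply get no similarity edges —
missing is not the same as dissimilar.

Two miRNA similarity sources are integrated by average ensemble: the mean
where both define a pair, the available value where only one does, zero
where neither does, unit diagonal. Similarity matrices enter the graph
through a sparsification rule — by default every off-diagonal entry
≥ 0.5 becomes an undirected weighted edge; a per-node top-k alternative
is available. The threshold keeps the graph sparse and deterministic; the
source data never prescribes an edge rule, so it is configurable.

## Random-walk learner

Uniform random walks (defaults: 10 walks per node, length 80) ignore
edge weights and types when stepping. Every ordered pair of nodes at
distance ≤ w (default window w = 2) inside a walk is a positive training
quadruple ⟨m, n, r, 1⟩ whose relation id r is the sequence of edge types
traversed between the two nodes; in this schema the edge type between two
adjacent walk nodes is determined by their node types. Each positive
yields 5 negatives by replacing n with a uniformly random node of the
same type, resampled while the corrupted triple coincides with an
observed positive (a corruption type with a single candidate node cannot
escape this check and is accepted as-is).

The classifier scores
`P(r|m,n) = σ(Σ_k W_M[m]_k W_N[n]_k f01(W_R[r])_k)`, where `f01` is an
elementwise logistic squashing keeping relation vectors in [0, 1] —
chosen for differentiability, since only the [0, 1] range is prescribed.
No bias term is used. Training maximises the per-sample log-likelihood
`L log P + (1−L) log(1−P)` by per-sample stochastic gradient ascent
(numba-compiled loop; samples reshuffled each epoch; learning rate 0.025
decaying linearly to ~0 over all updates). The start-role matrix `W_M`
is the node embedding output; `W_N` is kept separate (tying is a config
option). Weights initialise uniformly in ±0.5/dim. Per-sample analytic
gradients are exposed separately and are finite-difference-checked in the
test suite.

## Adversarial learner

The discriminator holds one embedding per node and one square matrix per
relation and scores a triple as `σ(e_u^T M_r v)`. The generator holds its
own node embeddings and relation matrices and fabricates a neighbour for
(u, r) as `tanh(e_u^gen M_r^gen + ε)`, ε ~ N(0, σ²I) with σ = 0.1, so its
fakes live in embedding space rather than being existing nodes. Per
epoch (default 50) the discriminator takes 10 minibatch updates — real
triples as true, relation-corrupted or node-corrupted triples as false,
generator fakes as false — and the generator takes 10 updates ascending
log D on its fakes.

Two design points were forced by experiments on the reference synthetic
network. First, with exactly one edge type per endpoint-type pair (the
situation in this 3-type schema) a wrong-relation negative never exists;
skipping the term entirely leaves the discriminator with only
real-vs-generated contrast, which it can satisfy without learning which
real pairs stand in a relation — true triples and random real pairs then
score identically (~0.5) no matter how long training runs. The negative
term therefore falls back to corrupting the neighbour node
(type-preservingly) whenever no wrong relation is available. Second,
gradient scaling: each node-embedding row accumulates the summed
per-sample gradients of the batch (per-sample SGD semantics at stale
weights), while the shared relation matrices — which receive contributions
from every sample — take the batch-mean step. Averaging the node
gradients over the batch as well shrinks each row's effective step by the
batch size and freezes training at initialisation. Learning rates default
to 0.01; discriminator node embeddings are the output, as they are the
vectors the adversarial game actually grounds against real data.

## Merging, pair vectors, datasets

The two embedding matrices are merged per node: concatenation (default;
output dim is the sum, 32+32 = 64), elementwise mean, or elementwise
product. An (SM, miRNA) pair becomes one vector through Hadamard product
(default), average, difference, or absolute difference. Balanced datasets
pair all positives with `⌊ratio·|positives|⌋` negatives drawn uniformly
without replacement from the unobserved cells of the SM × miRNA grid,
where the grid is restricted to entities with at least one association
edge. Negatives are not degree-matched — the sampling is deliberately the
plain uniform rule. Nodes lacking an embedding row are excluded with a
warning.

## Classification and evaluation

LightGBM (200 trees, depth ≤ 6, learning rate 0.1, seeded, single
thread) is the default classifier; Gaussian naive Bayes, logistic
regression, kNN (k = 5) and AdaBoost (100 stumps) are baselines. The
spec of metrics: recall/precision/accuracy/F1 at probability threshold
0.5 (no threshold is prescribed by the protocol, 0.5 is the natural
choice for balanced data), AUC as the trapezoid under the ROC curve and
AUPR as the step-wise integral of the precision–recall curve, both with
tied scores grouped into a single operating point so the values are
exact functions of the ranking, checkable against brute-force
pair-counting and step-integration oracles (and cross-checked against
scikit-learn in the tests). Cross-validation uses a stratified
pair-level split whose fold assignment is keyed on the pair ids, not row
order: within each class, pairs are sorted, shuffled with the seeded
generator, and dealt round-robin into k folds. Fold metrics are computed
on the held-out fold and averaged. Candidate ranking scores every
embedded miRNA not already associated with the probe SM and sorts by
descending probability, ties broken lexicographically.

## Synthetic data

Every entity draws a latent unit vector (dimension 4 by default).
Association edges are Bernoulli with probability `σ(a·cos + b)` in the
latent cosine; the gain is fixed at a = 6 and the intercept b is solved
by bisection so the mean probability equals the target density (0.05 by
default over 60 SMs × 100 miRNAs ≈ 300 positives — large enough to
stratify into 10 folds, small enough for minute-scale runs). Similarity
matrices are the clipped latent cosine plus symmetric Gaussian noise
(σ = 0.1), unit diagonal. The disease tree table is built by recursively
bisecting disease latents (depth 3, split on the principal axis at the
median, deterministic sign convention) so DAG similarity correlates with
latent similarity; each disease's tree number is its cluster path plus a
unique leaf segment. A configurable fraction of SM–miRNA positives can
be withheld before the graph is built, for hold-out evaluation.

What the generator does *not* emulate: the scale and degree skew of
curated databases, name noise beyond mature/precursor folding, biased
(study-driven) missingness, or correlated measurement error between the
similarity sources. Passing tests therefore demonstrate that the
pipeline recovers planted low-rank structure end-to-end, not that it
attains any particular performance on curated data.

## Problem sizes and numerics

Tests and the acceptance script run the reference network
(60/100/40 entities, density 0.05) with both learners at 32 dimensions;
five seeds for the end-to-end checks. Degenerate inputs are errors, not
silent defaults: empty graphs, single-class datasets, k larger than a
class, similarity thresholds outside [0, 1], cycles in a disease DAG
(reported with an offending edge), conflicting node types (reported with
the id). Training aborts on non-finite losses. Embedding I/O round-trips
at 8 significant digits; node ids may contain spaces (disease names), so
the word2vec-text reader treats the trailing `dim` fields as the vector.

## Known limitations

- The adversarial learner is consistently the weaker single source on
  the synthetic benchmark; it contributes complementary rather than
  dominant signal, and the merged features track the better single
  learner.
- CV pairs share entities across folds (pair-level split, as in the
  underlying protocol); cold-start performance for unseen SMs is not
  measured.
- Uniform negative sampling may label some true-but-unobserved
  associations negative; reliable-negative mining is out of scope.
- Walks ignore edge weights by default; weight-proportional stepping is
  available but untuned.
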