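# Methods

## Model

The package treats disease-gene prioritization as binary node
classification on a weighted undirected gene network. Three assumptions
drive the design:

1. **Guilt by association** — disease genes interact with each other more
   densely than with unrelated genes, so network proximity carries label
   information.
2. **Feature relevance** — per-gene features (tissue expression in the
   motivating application) differ systematically between classes.
3. **Complementarity** — walk-based embeddings capture global community
   structure; graph-convolutional encoding mixes local neighborhood
   structure with the features themselves. Fusing both should dominate
   either alone.

### Walk embedding branch

First-order weighted random walks: from vertex `v` the next vertex is a
neighbor drawn with probability proportional to the incident edge weight
(no restarts, no second-order biasing). The skip-gram objective for center
`v_i` is the negative log-likelihood of the context vertices inside a
sliding window, with conditional probabilities given by a softmax over
embedding inner products. Training uses the standard negative-sampling
estimator of this objective — 5 noise draws per positive pair from the
unigram^0.75 corpus distribution — as pair-level stochastic gradient
descent with a linearly decaying learning rate (0.025 → 1e-4), implemented
as a single-threaded numba kernel so that a fixed seed reproduces the
embedding bit for bit. The exact full-softmax loss (`skipgram_loss`) is kept
as a reference objective; the test suite verifies that training reduces it
on probe positions.

### Convolutional branch and classifier

The encoder propagates features through `D'^(−1/2)(W+I)D'^(−1/2)` (unit
self-loops added to the weighted adjacency, symmetric degree
normalization), followed by LeakyReLU with negative slope 0.2, applied
uniformly including the last encoder layer. The graph Laplacian `L = D − W`
is implemented as the standard spectral view of the network but is not
consumed by the encoder's forward pass.

The encoder carries no supervision of its own, so its weights are trained
end-to-end with the prediction network under the classification loss; the
walk embeddings are trained separately (they are label-free) and frozen.
The prediction network applies two hidden transforms (affine → batch
normalization → LeakyReLU) and an output transform with a two-class
softmax; the loss is binary cross-entropy on the positive-class
probability, clipped to `[1e−7, 1−1e−7]`. Batch normalization sits between
the affine transform and the activation; inference uses running statistics
(momentum 0.9) and is deterministic. All gradients (including through the
batch statistics and the encoder) are derived analytically and implemented
in NumPy; a finite-difference check at relative tolerance 1e−4 pins them
down in the test suite.

Training is transductive and full-graph: the encoder propagates over every
node of the network while the loss is evaluated on labelled training rows
only. Test-fold genes therefore contribute their features and connectivity
(never their labels) during training, as is standard for graph-convolutional
node classification.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| `window` | 10 | skip-gram context half-width |
| `skipgram_iterations` | 10 | passes over the (center, context) pairs |
| `walks_per_node` / `walk_length` | 10 / 40 | common walk-corpus practice; config-exposed |
| `embedding_dim` | 64 | walk-embedding width |
| `gcn_layers` | 3 | 2/4 available for the depth ablation |
| `gcn_hidden` | 64 | encoder width per layer |
| `dnn_hidden` | (64, 32) | hidden widths; output is always 2 logits |
| `max_epochs` / `patience_epochs` | 200 / 50 | early stopping on validation loss; `max_epochs=50` reproduces the strict fixed-budget schedule, under which the 50-epoch patience never binds |
| `learning_rate` | 1e−3 | Adam with default moment parameters |
| `validation_fraction` | 0.1 | stratified, seeded split of the training genes |
| `k` / `repeats` | 10 / 10 | cross-validation protocol |
| `restart_prob` | 0.5 | RWR baseline restart probability |

The "50 train epochs" and "stop after 50 epochs without improvement"
prescriptions are contradictory if read together (the patience could never
bind); the package resolves this as `max_epochs=200` with `patience=50` by
default and documents the strict 50-epoch schedule as a config option.

## Synthetic data

`synthetic_data` generates a planted-partition graph: an edge joins a
same-class pair with probability `p_in` and a cross-class pair with
`p_out`, weights uniform on (0, 1] in the style of probabilistic
functional-association scores. Nodes left isolated by the Bernoulli draw
are re-wired to one random same-class partner (the no-isolated-gene
invariant of the network type; disabling re-wiring instead prunes them).
Feature `j` of gene `i` is `Normal(δ·z_i·s_j, σ²)` with `z_i` the label and
`s_j` a fixed random sign per feature. The default configuration —
`n_pos = n_neg = 142`, `p_in = 0.10`, `p_out = 0.02`, `δ = 1.5`, `σ = 1`,
30 features — mirrors the 142+142-gene design of the motivating study at
desk scale and constitutes the "strong signal" study conditions used by the
acceptance tests.

What the generator does **not** emulate: scale (real functional networks
have tens of thousands of genes and the positives are a tiny minority, not
half the nodes), degree heterogeneity (real networks are heavy-tailed;
planted partitions are approximately regular), weight–label dependence
beyond block structure, and correlated or batch-structured features.
Passing tests therefore demonstrate that the implementation recovers the
signal the model assumes when that signal is present — not that the method
attains any particular accuracy on real curated datasets, whose published
scores depend on external data and preprocessing outside this package's
scope.

## Evaluation protocol

Stratified k-fold assignment is implemented in-package: within each class
fold sizes differ by at most one, and the folds receiving each class's
remainder are staggered across classes so overall fold sizes also differ by
at most one (at 142+142 and k=10: folds of 28 or 29 genes, 14–15 per
class). Negatives are fixed per dataset; each repeat draws a fresh
partition. AUROC uses the rank (Mann–Whitney) formulation with half credit
for ties; AUPR is the area under the precision–recall step curve with no
interpolation — both delegated to scikit-learn and pinned against
brute-force oracles (pairwise comparison; threshold sweep) in the tests.
RWR solves `p = (1−r)·P^T p + r·e` by power iteration to an L1 residual
below 1e−10, with `P` the row-normalized transition matrix and `e` uniform
over the seed genes; a fold's test genes are scored by proximity to the
training-fold positives, no training involved.

Walk embeddings are label-free, so `run_cv` trains them once per dataset
and shares them across folds, repeats and methods; classifier and encoder
are retrained from scratch per fold with fold-specific seeds.

## Numerical choices

- Node order is the lexicographic sort of gene identifiers, fixed at build
  time; every matrix and embedding row follows it.
- Duplicate edge records with equal weight collapse silently (edge lists
  often list both directions); unequal duplicates raise — fail loud on
  dirty input. Self-edges in input raise; self-loops exist only inside the
  augmented adjacency.
- The normalized adjacency is computed as `A' ⊙ outer(d^(−1/2), d^(−1/2))`,
  which is exactly symmetric in floating point. Note it is *not* invariant
  to rescaling all edge weights, because the self-loop weight is fixed at
  1 — rescaling shifts mass between self-loop and neighbors by design.
- Softmax is computed with max-subtraction; two-class softmax + binary
  cross-entropy gives the gradient `(p − y)` on the positive logit.
- Batch normalization uses ε = 1e−5 and biased batch variance; with
  full-batch training (the default) every epoch normalizes over the whole
  training fold.
- Early stopping requires strict improvement; patience 0 stops at the
  first non-improving epoch; the returned parameters are deep copies taken
  at the best validation epoch (including batch-norm running statistics).
- Prediction ties at probability 0.5 resolve to the positive class.
- Seeds: every stochastic component (walks, skip-gram, simulation, fold
  assignment, initialization, validation split) takes an explicit seed;
  fold-level training seeds are derived as `seed + 977·repeat + fold`.

## Test and acceptance problem sizes

Unit and property tests run on graphs of 2–30 nodes. The acceptance tests
use the full 142+142 default conditions for null calibration (ten
label-permuted replicates, each a fresh permutation — a single fixed
permutation would retain a chance degree–label correlation of order 0.03
AUROC that fold averaging cannot remove) and for signal recovery (five
simulation seeds, one 10-fold round each). The end-to-end reproducibility
check runs the command-line pipeline twice at 20+20 genes and compares
output bytes. The depth ablation and over-smoothing checks use fixed
30-node graphs.

## Known limitations

- Dense adjacency matrices throughout: fine into the low thousands of
  genes, not intended for full-interactome scale without sparsification.
- The skip-gram trainer is single-threaded by design (bit-reproducibility
  over throughput); multi-worker training would break it.
- Transductive training means a trained model scores only genes present in
  the network it was trained on; there is no inductive out-of-network
  prediction.
- The KBMF baseline of the motivating comparison is out of scope; random
  forest can be run externally on the same folds but is not wired in.
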