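# deeprw — network-based disease-gene prioritization

`deeprw` predicts disease-associated genes from a weighted gene-interaction
network. It is aimed at computational biologists who have (a) a
HumanNet-style edge list of functional gene–gene associations, (b) a list of
genes known to be associated with a disease (e.g. curated from DisGeNET) plus
a matched list of unrelated genes, and (c) per-gene feature vectors such as
tissue-expression profiles. The underlying premise is guilt by association:
genes that interact closely with known disease genes are themselves more
likely to be disease-associated.

## Method

Let `G = (V, E)` be the undirected gene network with symmetric weighted
adjacency `W` (`W_ij = W_ji = w`, the association score). Genes without any
positive-weight interaction are removed. Two vertex representations are
learned:

1. **Walk embedding.** Truncated random walks `[v_1, v_2, …]` are sampled
   from every vertex, each step choosing a neighbor with probability
   proportional to the edge weight. A skip-gram model is trained on the
   walks: for a center vertex `v_i` the loss is
   `L(v_i) = −Σ_j log P(v_cj | v_i)` over the at most `2·window` context
   vertices, with `P` a softmax over vector inner products (optimized by
   negative sampling; the exact softmax objective is kept as a reference
   loss). Window 10, 10 training iterations.

2. **Graph-convolutional encoding.** Node features `X` are propagated
   through the symmetrically normalized, self-loop-augmented adjacency:
   each of the 3 layers computes `H' = σ(D'^(−1/2) (W+I) D'^(−1/2) H Θ)`
   with `σ` = LeakyReLU (`max(0,x) + 0.2·min(0,x)`). Three layers balance
   neighborhood context against over-smoothing — with many layers all node
   representations collapse toward a common value (`examples/03` shows
   this collapse directly).

The two vectors are concatenated per gene and classified by a three-layer
feed-forward network (affine → batch-norm → LeakyReLU twice, then affine →
softmax over 2 classes), trained with binary cross-entropy
`Loss = −y·log p − (1−y)·log(1−p)`, Adam, and early stopping on a held-out
validation split. The encoder is trained jointly with the classifier; walk
embeddings are trained unsupervised and stay frozen.

Evaluation is repeated stratified 10-fold cross-validation with AUROC and
AUPR, against a random-walk-with-restart (RWR) baseline
(`p = (1−r)·P^T p + r·e`, seeds = training positives) and three ablations
(walk branch only, encoder branch only, raw features only).

Everything is testable offline: `deeprw.synthetic_data` generates
planted-partition networks (within-class edge probability `p_in` > cross-class
`p_out`) with label-correlated Gaussian features, mirroring the 142+142-gene
design of the motivating study.

## Worked example

`examples/` contains one short script per capability. Cross-validating all
methods on a small strong-signal synthetic dataset
(`python examples/05_cross_validation.py`) prints:

```
method            mean AUROC  mean AUPR   (1.0 = perfect ranking of held-out genes)
deepRW            0.988       0.992
withoutGCN        0.956       0.970
withoutDeepWalk   0.984       0.988
dnnOnly           1.000       1.000
rwr               0.916       0.936

RWR trails the full model by 7.28% in mean AUROC on this dataset.
```

Each row is the mean over all held-out folds of the probability that a
random positive gene outranks a random negative one (AUROC) and the area
under the precision–recall step curve (AUPR). On this synthetic dataset both
the network signal and the feature signal are strong, so all learned methods
rank well and the propagation-only RWR baseline trails them.

The same pipeline is available from the shell:

```sh
deeprw simulate --out data/ --seed 1
deeprw evaluate --data data/ --out results/ --seed 1
deeprw train    --data data/ --out model.npz --seed 1
deeprw predict  --model model.npz --genes data/positives.txt --out scores.tsv
```

All commands are deterministic for a fixed `--seed` (single-worker
training throughout).

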