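"""Build a weighted gene network and inspect its matrix views.

A handful of HumanNet-style association records (gene_a, gene_b,
probability-like weight) are assembled into an undirected network;
zero-weight records and genes left without any interaction are pruned.
The Laplacian and the symmetrically normalized, self-loop-augmented
adjacency that the convolutional encoder propagates through are
printed for the toy graph.
"""

import numpy as np

from deeprw import build_network, laplacian, normalize_adjacency

edges = [
    ("BRCA2", "TP53", 0.90),
    ("TP53", "EGFR", 0.60),
    ("EGFR", "KRAS", 0.75),
    ("KRAS", "TP53", 0.40),
    ("ORPHAN1", "ORPHAN2", 0.0),  # zero weight: both genes get pruned
]
net = build_network(edges)
print("nodes:", net.node_ids)
print("edges:", net.edge_count)

np.set_printoptions(precision=3, suppress=True)
print("\nLaplacian L = D - W (row sums are 0):")
print(laplacian(net))

norm = normalize_adjacency(net)
print("\nNormalized augmented adjacency D'^(-1/2) (W + I) D'^(-1/2):")
print(norm.matrix)
print("\nSpectral radius (<= 1, so deep propagation cannot blow up):",
      round(float(np.max(np.abs(np.linalg.eigvalsh(norm.matrix)))), 6))
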