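"""Show why the convolutional encoder uses three layers, not sixteen.

Each encoder layer averages every node's representation with its
neighborhood through the normalized adjacency. Stacking many layers
over-smooths: all representations converge toward a common value and
the nodes become indistinguishable. The script propagates fixed random
features through increasingly deep stacks (shared weights) and prints
the mean pairwise distance between node representations at each depth.
"""

import numpy as np

from deeprw import GCNParams, SimulationConfig, gcn_forward, normalize_adjacency, simulate_network

net, _ = simulate_network(SimulationConfig(n_pos=15, n_neg=15, p_in=0.3, p_out=0.1, seed=8))
a_hat = normalize_adjacency(net)

rng = np.random.default_rng(0)
x = rng.standard_normal((net.n_nodes, 8))
w = rng.standard_normal((8, 8)) / np.sqrt(8)

print("depth  mean pairwise distance between node representations")
for depth in (1, 2, 3, 4, 8, 16):
    h = gcn_forward(x, a_hat, GCNParams(layer_weights=[w] * depth))
    spread = np.linalg.norm(h[:, None, :] - h[None, :, :], axis=-1).mean()
    print(f"{depth:5d}  {spread:.4f}")
print("\nThe spread shrinks with depth: representations collapse together "
      "(over-smoothing), which is why the default encoder stops at 3 layers.")
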