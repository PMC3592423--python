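"""Infer an MI network from simulated expression data and prune it.

Builds a 40-gene ground-truth network, simulates 120 expression
observations, infers the co-expression network by rank-transformed
B-spline mutual information with a pooled permutation null, removes
candidate indirect edges with the data processing inequality, and compares
the result with the truth.
"""

from mignet import all_pairs_mi, apply_dpi, score_prediction, summarize
from mignet.synthetic import sample_topology, simulate_expression

truth = sample_topology(n=40, avg_degree=2, seed=1)
expr = simulate_expression(truth, kind="linear", m=120, noise_sd=0.1, seed=1)

net = all_pairs_mi(expr, bins=10, order=3, epsilon=1e-3, P_perm=10_000, seed=1)
pruned = apply_dpi(net, tolerance=0.0)

score = score_prediction(pruned, truth)
summary = summarize(pruned, hub_min_degree=5)

print(f"truth edges:     {truth.number_of_edges()}")
print(f"edges called:    {net.number_of_edges()} "
      f"(MI threshold {net.graph['threshold']:.4f} nats)")
print(f"after DPI:       {pruned.number_of_edges()}")
print(f"precision {score.precision:.3f}  recall {score.recall:.3f}  "
      f"F {score.f_score:.3f}")
print(f"density {summary.density:.4f}  average degree "
      f"{summary.average_degree:.2f}  clustering {summary.clustering:.3f}")
# precision/recall near 1 mean the significant-MI edges, after removing
# triangle-closing indirect edges, recover the simulated regulatory links
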