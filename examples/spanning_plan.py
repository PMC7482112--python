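"""Plan the propagation order over phenotype missingness patterns.

The weight between two phenotypes is the number of samples observed for one
but not the other — exactly the number of rank-1 factor edits needed to move
between their kinship submatrices.  A minimum spanning tree of these weights,
walked breadth-first from the least-observed phenotype, orders the work.
"""

import numpy as np

from kgen import apply_mar_mask, build_graph, plan_propagation

Y = apply_mar_mask(np.zeros((200, 8)), rate=0.05, seed=3)

graph = build_graph(Y)
print("pairwise modification counts (symmetric-difference weights):")
print(graph.weights)
print("r (max pairwise weight):", graph.max_pairwise_weight)

plan = plan_propagation(Y)
print(f"\nroot: phenotype {plan.root}")
print("breadth-first edges (source -> target, weight):")
for (src, tgt), w in zip(plan.edges, plan.edge_weights):
    print(f"  {src} -> {tgt}   {w}")
print("total weight:", plan.total_weight,
      "(rank-1 modifications needed to reach all 8 factors from the root)")
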