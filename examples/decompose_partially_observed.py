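"""Factor kinship submatrices for 40 phenotypes with scattered missingness.

Simulates a Wishart kinship matrix (identity mean, as for a study typed at
many independent markers) and phenotypes missing at random, then compares the
spanning-tree propagation against one full decomposition per phenotype.
"""

import numpy as np

from kgen import apply_mar_mask, max_entrywise_diff, run_kgen, run_naive, simulate_wishart_kinship

n, d = 400, 40
K = simulate_wishart_kinship(n, dof=10_000, seed=1)
Y = apply_mar_mask(np.zeros((n, d)), rate=0.01, seed=2)

res = run_kgen(K, Y)
naive = run_naive(K, Y)

print(f"samples n={n}, phenotypes d={d}, MAR rate 1%")
print(f"root phenotype: {res.plan.root} (fewest observed samples)")
print(f"spanning-tree weight: {res.plan.total_weight} rank-1 modifications")
print(f"full decompositions: {res.counters.full_decompositions} "
      f"(the naive method needs {naive.counters.full_decompositions})")
print(f"max entrywise |L_kgen - L_naive| over all phenotypes: "
      f"{max_entrywise_diff(res, naive):.3e}")
# The single cubic-cost decomposition plus ~2*masked-count quadratic-cost
# modifications reproduce all 40 factors to near machine precision.
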