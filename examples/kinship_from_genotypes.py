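"""Build a genomic relationship matrix from dosages and factor it.

The kinship entry for a pair of samples is their covariance over markers
after centring dosages at twice the population minor allele frequency and
scaling by the binomial variance 2*rho*(1-rho).
"""

import numpy as np

from kgen import compute_kinship, full_cholesky, simulate_genotypes

geno = simulate_genotypes(n=10, m=500, maf_range=(0.05, 0.5), seed=4)
K = compute_kinship(geno)

print(f"{geno.n_samples} samples x {geno.n_markers} markers")
print("kinship matrix (2 decimals):")
print(np.round(K.values, 2))

eigs = np.linalg.eigvalsh(K.values)
print(f"eigenvalue range: [{eigs.min():.3f}, {eigs.max():.3f}] (PSD by construction)")

L = full_cholesky(K.values)
print("factor reconstruction error:",
      f"{np.abs(L.reconstruct() - K.values).max():.3e}")
# With m >> n the Gram matrix is comfortably positive definite and the
# diagonal sits near 1, as for unrelated samples.
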