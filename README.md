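# kgen

Fast Cholesky factors of kinship submatrices across partially observed
phenotypes, for multiphenotype mixed-model GWAS workflows.

## The problem

Mixed-model association analyses treat the n×n genetic similarity (kinship)
matrix **K** as the covariance of a random genetic effect, so every
likelihood evaluation needs solves against K — in practice, the triangular
factor **L** with L·Lᵀ = K and the whitened phenotype L⁻¹y. With d
phenotypes that are each *partially observed*, marginalizing out the missing
samples replaces K by a different principal submatrix per phenotype,

    K_j = K[obs(j), obs(j)],        y_j = y[obs(j), j],

where obs(j) is the set of samples observed for phenotype j. Decomposing
each K_j from scratch costs O(d·n³) and dominates large multiphenotype
studies.

## The algorithm

When missingness is sparse, the observation sets of different phenotypes are
nearly identical, and the factor of one K_j can be turned into the factor of
another by a handful of O(n²) rank-1 operations: deleting the row/column of a
sample observed only in the source, and inserting the kinship column of a
sample observed only in the target. The number of operations between
phenotypes j₁ and j₂ is the symmetric-difference size
#(obs(j₁)\obs(j₂)) + #(obs(j₂)\obs(j₁)).

This package builds the complete graph over phenotypes weighted by those
counts, extracts a minimum spanning tree (Kruskal), roots it at the
phenotype with the fewest observed samples, and walks its edges
breadth-first: one full O(n³) decomposition at the root, then O(n²)
propagation along each of the d−1 edges, for a total of

    O(n³ + r·d·n²),    r = max pairwise weight,

instead of O(d·n³). An edge needing more than a threshold number of
modifications (default 100) is "short-circuited" — the target submatrix is
decomposed from scratch instead — which keeps the method efficient under
blockwise missingness designs where whole phenotype categories share a large
masked sample subset. Completed factors can spill to disk through a
least-recently-used store; the breadth-first order keeps each edge's source
factor recently touched.

## Worked example

`examples/decompose_partially_observed.py` simulates a Wishart kinship
matrix (identity mean, 10,000 degrees of freedom — a study typed at 10,000
markers) and 40 phenotypes missing at random at 1%, then runs both methods:

```
samples n=400, phenotypes d=40, MAR rate 1%
root phenotype: 21 (fewest observed samples)
spanning-tree weight: 163 rank-1 modifications
full decompositions: 1 (the naive method needs 40)
max entrywise |L_kgen - L_naive| over all phenotypes: 6.661e-16
```

One cubic-cost decomposition plus 163 quadratic-cost modifications replace
40 cubic decompositions, and every propagated factor matches its freshly
decomposed counterpart to near machine precision. The other scripts in
`examples/` show the rank-1 factor edits in isolation, the spanning-tree
plan, kinship construction from genotype dosages, and phenotype whitening.

A thin CLI wraps the same library:

```
kgen decompose --kinship K.txt --pheno Y.tsv --out factors/ --compare-naive
kgen whiten    --factors factors/ --pheno Y.tsv --out whitened.tsv
kgen benchmark --n 1000 --d 100 --rates-bp 1,5,10,15,20 --replicates 5
```

Phenotype tables are whitespace-delimited text with the literal string `NA`
marking missing entries; kinship matrices are dense text or packed binary
with a JSON sidecar.

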