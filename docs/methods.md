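# Methods

## Model and procedure

The package computes, for each of d phenotypes, the lower Cholesky factor
L_j of the kinship submatrix K_j = K[obs(j), obs(j)], where obs(j) is the
set of samples with an observed measurement for phenotype j. Restricting K
to the observed samples is exact marginalization of the missing samples
under the Gaussian mixed-model prior: it adds no assumptions beyond the
model already in use, unlike imputation.

Rather than d independent O(n³) decompositions, the factors are propagated:

1. **Missingness graph.** Complete graph on phenotypes; the weight between
   j₁ and j₂ is #(obs(j₁)\obs(j₂)) + #(obs(j₂)\obs(j₁)), the exact number of
   rank-1 row/column edits separating their factors. Weights are computed in
   one Gram product of the boolean observed-mask.
2. **Minimum spanning tree.** Kruskal with union-find; candidate edges are
   sorted by (weight, smaller vertex, larger vertex) so ties resolve
   deterministically and plans are reproducible.
3. **Root.** Default: the phenotype with the fewest observed samples
   (smallest — hence cheapest — cubic decomposition), ties to the smallest
   index. A `max-obs` mode roots at the most-observed phenotype instead;
   both are exposed because either convention is defensible and the MST —
   hence the total modification count — is the same under both.
4. **Breadth-first edge order.** Children visited in ascending phenotype
   index. Breadth-first matters when factors spill to disk: the source
   factor of the next edge is always the most recently completed or a
   sibling's parent, so an LRU store rarely reloads from disk.
5. **Propagation.** One merged ascending scan over original sample indices
   per edge, with a cursor into the evolving factor: samples in both
   observation sets advance the cursor, samples only in the source are
   deleted at the cursor, samples only in the target are inserted there with
   the kinship column restricted to the post-insertion sample set (the
   unique vector for which the insertion contract reproduces
   K[S∪{i}, S∪{i}]). The scan terminates with the factor's sample ids equal
   to the target observation set, which is asserted.
6. **Short circuit.** An edge whose weight strictly exceeds a threshold
   (default 100 modifications) is replaced by a fresh decomposition of the
   target submatrix. Quadratic-cost edits beat a fresh decomposition only
   while the edit count is small relative to n; under blockwise missingness
   the between-block edges are exactly the ones worth short-circuiting.
   Threshold 0 degenerates to the naive method; ∞ disables the circuit. The
   default of 100 reflects the crossover observed on commodity hardware and
   is configurable.

Whitening is a separate step: x = L_j⁻¹ y_j by forward substitution, so that
xᵀx = y_jᵀ K_j⁻¹ y_j, the quadratic form mixed-model likelihoods consume.
The propagation itself never reads phenotype values — only the missingness
pattern.

## Factor numerics

Lower-triangular convention throughout: L·Lᵀ = K with positive diagonal
(unique for positive-definite K). Full decompositions call LAPACK `dpotrf`;
a failure is reported with the 0-based index of the first non-positive
pivot. The rank-1 operations are implemented directly:

- **Update** (K + vvᵀ): Givens-rotation sweep, column by column.
- **Downdate** (K − vvᵀ): hyperbolic-rotation sweep with a stability guard —
  the sweep aborts when 1 − (v_k/L_kk)² ≤ 1e−13, signalling loss of positive
  definiteness at that pivot.
- **Delete at position i:** the leading block is reused unchanged; the
  trailing block is rank-1 *updated* with the deleted column segment. In
  exact arithmetic this cannot fail (a principal submatrix of a PD matrix is
  PD).
- **Insert at position i:** triangular solve for the new row
  (a = L₁₁⁻¹ v[:i]), pivot d = √(v_i − aᵀa) — non-positive pivot means the
  augmented matrix is not PD — new column below (v[i+1:] − L₃₁a)/d, then a
  rank-1 *downdate* of the trailing block.

Each modification costs O(order²); an instrumented operation tally exposed
by the module verifies the quadratic growth in tests. The sweeps are
compiled scalar kernels (numba), with a numpy implementation kept alongside
as the reference semantics and fallback — at typical factor orders the
per-row interpreter overhead of a pure-numpy sweep would otherwise exceed
the flops themselves. All positions in the Python API are 0-based.

Because the Cholesky factor of a PD matrix is unique, these operators are
fully specified by their input/output contracts; every one is tested
entrywise against a fresh decomposition of the explicitly modified matrix
(tolerance 1e−12 on well-conditioned random instances, orders 2–50, >100
property-based cases) plus roundtrip identities (update∘downdate,
insert∘delete).

## Synthetic data: what it emulates and what it does not

- **Kinship:** K = XᵀX/dof with X a (dof × n) standard-normal matrix, i.e. a
  Wishart draw scaled so E[K] = I — the spectrum of a GRM for n unrelated
  samples typed at `dof` independent markers. Default dof = 10,000. For
  dof < n the draw is singular; the simulator exposes a `ridge` parameter
  (recommended 1e−6 in that regime) since the engine requires strict
  positive definiteness. Real GRMs with relatedness, population structure or
  LD have heavier-tailed spectra and off-diagonal blocks; nothing in the
  algorithm depends on the spectrum beyond positive definiteness, but the
  accuracy results here are demonstrated on the Wishart family only.
- **Genotypes:** per-marker MAF uniform on (0.05, 0.5), dosages
  Binomial(2, MAF) i.i.d. across samples — no LD, no structure; this
  generator exists to exercise the GRM construction, not to model a
  population.
- **Missingness:** (a) missing at random, each entry masked independently at
  a fixed basis-point rate, with a column-emptying mask resampled (up to 100
  attempts) because an empty observation set has no factor; (b) blockwise,
  consecutive blocks of `block_size` phenotypes sharing one uniformly drawn
  masked sample subset of size round(mask_frac·n) (round-half-even for
  platform determinism). Real cohort missingness is usually a mixture and
  not independent of phenotype value (MNAR); the method only ever uses the
  missingness *pattern*, so those mechanisms affect the statistics
  downstream, not the factorization accuracy shown here.

Passing tests therefore demonstrate numerical agreement and the claimed
operation structure under these designs; they do not certify performance on
GRMs with near-singular directions (see Limitations).

## Numerical choices

- Downdate/insertion pivot guard: relative threshold 1e−13 (configurable at
  module level). Well-conditioned inputs sit far from it; it exists to turn
  slow loss of definiteness into a clear error naming the pivot.
- Symmetry: kinship construction and I/O symmetrize (K + Kᵀ)/2 and reject
  input asymmetric beyond 1e−8 (text I/O) or 1e−12 (in-memory construction).
- Determinism: every simulator takes a seed; Kruskal and breadth-first
  orders carry explicit tie-breaks; `dpotrf` and the sweeps are
  deterministic, so repeated runs produce bit-identical factors, and the
  factor store's packed-triangle spill format (little-endian float64 with a
  sha256-checksummed JSON sidecar) reloads factors bit-identically.
- Degenerate inputs: d = 1 yields an empty plan (root only); zero-weight
  edges (identical observation sets) copy the source factor without
  modifications; an all-missing phenotype column is rejected with the column
  index.

## Problem sizes in the shipped checks

The test suite and acceptance script run the accuracy grid at n = 500,
d = 100 (rates 1–20 bp, five replicates per rate) and the blockwise design
at n = 2000, d = 100 — the same structure as the full-scale experiments the
method targets, at sizes a laptop handles in minutes. The blockwise runs use
disk-spilling factor stores so resident memory stays at a few factors
regardless of d.

## Known limitations

- Edits are strictly rank-1 and sequential; no blocked/batched rank-k
  variant, no sparse or banded factors, and no pivoted/semidefinite
  handling — K must be strictly PD on every observation set.
- Propagation is single-threaded by design (BLAS may parallelize within
  operations). Wall-clock gains over the naive method depend on the
  BLAS/hardware balance between one O(n³) call and many O(n²) edits; the
  benchmark harness and acceptance script report times but the package
  asserts only numerical agreement and operation counts.
- No variance-component estimation or LMM fitting: the package produces the
  factors and whitened phenotypes such methods consume.
- File formats are intentionally minimal (text tables, packed binary +
  sidecar); no PLINK/VCF/GCTA-GRM parsing.
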