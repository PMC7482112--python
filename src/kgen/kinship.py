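"""Kinship (genetic similarity) matrices and simulated study data.

The kinship matrix used here is the genomic relationship matrix centred at
population-level minor allele frequencies: with dosages ``G`` (copies of the
minor allele, 0/1/2) over ``m`` markers and population frequencies ``rho``,

    K[i1, i2] = (1/m) * sum_l (G[i1,l] - 2 rho_l) (G[i2,l] - 2 rho_l)
                               / (2 rho_l (1 - rho_l))

which is the Gram matrix of the standardized genotypes and hence positive
semidefinite by construction.

The simulators emulate the study conditions under which the spanning-tree
propagation is evaluated: Wishart-distributed kinship matrices with identity
mean (a study typed at ``dof`` markers), missing-at-random phenotype masks at
basis-point rates, and blockwise masks in which consecutive blocks of
phenotypes share one masked sample subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "PhenotypeMatrix",
    "compute_kinship",
    "estimate_allele_freqs",
    "simulate_wishart_kinship",
    "simulate_genotypes",
    "apply_mar_mask",
    "apply_blockwise_mask",
]


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with per-marker population frequencies.

    ``dosages`` is ``(n_samples, n_markers)`` with entries in {0, 1, 2};
    ``allele_freqs`` holds the population minor allele frequency of each
    marker, strictly inside (0, 1).
    """

    dosages: np.ndarray
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=np.float64)
        if self.dosages.ndim != 2 or self.dosages.shape[1] < 1:
            raise ValueError("dosages must be a 2-d matrix with at least one marker")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must take values in {0, 1, 2}")
        if self.allele_freqs.shape != (self.dosages.shape[1],):
            raise ValueError("allele_freqs length must equal the number of markers")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]


@dataclass
class KinshipMatrix:
    """Symmetric n-by-n genetic covariance matrix.

    Positive definiteness is not checked at construction; factorization-time
    checks in the engine report a failure with the offending pivot instead.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("kinship matrix must be symmetric (|K - K.T| <= 1e-12)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.intp)
        return self.values[np.ix_(idx, idx)]


@dataclass
class PhenotypeMatrix:
    """n-by-d phenotype matrix with NaN marking missing entries.

    ``obs_sets`` gives, per column j, the strictly increasing array of row
    indices observed for that phenotype.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("phenotype matrix must be 2-d")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean (n, d) matrix, True where the entry is observed."""
        return ~np.isnan(self.values)

    @property
    def obs_sets(self) -> list[np.ndarray]:
        mask = self.observed_mask
        return [np.flatnonzero(mask[:, j]) for j in range(self.n_phenotypes)]

    def require_no_empty_columns(self) -> None:
        counts = self.observed_mask.sum(axis=0)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            raise ValueError(
                f"phenotype column {empty[0]} has no observed entries; "
                "every phenotype needs at least one observed sample"
            )


def compute_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix from dosages and population allele frequencies.

    Raises when any allele frequency is 0 or 1 (the standardization divides by
    ``2 rho (1 - rho)``), naming the offending marker.
    """
    rho = geno.allele_freqs
    bad = np.flatnonzero((rho <= 0.0) | (rho >= 1.0))
    if bad.size:
        raise ZeroDivisionError(
            f"marker {bad[0]} has allele frequency {rho[bad[0]]}; "
            "frequencies must lie strictly inside (0, 1)"
        )
    Z = (geno.dosages.astype(np.float64) - 2.0 * rho) / np.sqrt(2.0 * rho * (1.0 - rho))
    K = (Z @ Z.T) / geno.n_markers
    K = (K + K.T) / 2.0  # enforce exact symmetry against rounding
    return KinshipMatrix(K)


def estimate_allele_freqs(dosages: np.ndarray) -> np.ndarray:
    """Sample-mean allele frequency estimate, ``mean(dosage) / 2`` per marker.

    The kinship definition above centres at *population*-level frequencies;
    this sample-level estimator is a convenience deviation for data lacking
    population frequencies and is not used by the simulators.
    """
    dosages = np.asarray(dosages, dtype=np.float64)
    return dosages.mean(axis=0) / 2.0


def simulate_wishart_kinship(
    n: int, dof: int = 10_000, ridge: float = 0.0, seed: int | np.random.Generator = 0
) -> KinshipMatrix:
    """Wishart kinship draw with identity mean: ``K = X^T X / dof + ridge * I``.

    ``X`` is ``(dof, n)`` standard normal, so ``E[K] = I`` when ``ridge = 0``;
    this emulates a study typed at ``dof`` independent markers.  When
    ``dof < n`` the draw is singular — pass a small ridge (e.g. 1e-6) if the
    matrix must be strictly positive definite.
    """
    if n < 1 or dof < 1:
        raise ValueError("n and dof must be positive")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((int(dof), int(n)))
    K = (X.T @ X) / float(dof)
    K = (K + K.T) / 2.0
    if ridge:
        K[np.diag_indices_from(K)] += ridge
    return KinshipMatrix(K)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Binomial dosage fixture: per-marker MAF uniform on ``maf_range``,
    dosages Binomial(2, MAF) independently per sample and marker."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
    rng = np.random.default_rng(seed)
    rho = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, rho, size=(n, m))
    return GenotypeMatrix(dosages, rho)


def apply_mar_mask(
    Y: np.ndarray, rate: float, seed: int | np.random.Generator = 0
) -> PhenotypeMatrix:
    """Missing-at-random mask: each entry masked independently with probability
    ``rate``.

    A column whose mask would leave no observed entry is resampled (up to 100
    attempts) so that every phenotype keeps a non-empty observation set.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    Y = np.array(Y, dtype=np.float64, copy=True)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-d")
    rng = np.random.default_rng(seed)
    n, d = Y.shape
    mask = rng.random((n, d)) < rate
    for j in range(d):
        attempts = 0
        while mask[:, j].all():
            mask[:, j] = rng.random(n) < rate
            attempts += 1
            if attempts > 100:
                raise RuntimeError(
                    f"could not draw a non-empty observation set for column {j}"
                )
    Y[mask] = np.nan
    return PhenotypeMatrix(Y)


def apply_blockwise_mask(
    Y: np.ndarray,
    block_size: int,
    mask_frac: float,
    seed: int | np.random.Generator = 0,
) -> PhenotypeMatrix:
    """Blockwise mask: consecutive blocks of ``block_size`` phenotypes each get
    one shared masked sample subset of size ``round(mask_frac * n)``.

    The subset is drawn uniformly without replacement, independently per
    block; the last block may be smaller than ``block_size``.  The rounding is
    round-half-even for cross-platform determinism.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not 0.0 <= mask_frac < 1.0:
        raise ValueError("mask_frac must lie in [0, 1)")
    Y = np.array(Y, dtype=np.float64, copy=True)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-d")
    rng = np.random.default_rng(seed)
    n, d = Y.shape
    n_masked = int(np.round(mask_frac * n))
    for start in range(0, d, block_size):
        subset = rng.choice(n, size=n_masked, replace=False)
        Y[np.ix_(subset, np.arange(start, min(start + block_size, d)))] = np.nan
    return PhenotypeMatrix(Y)
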