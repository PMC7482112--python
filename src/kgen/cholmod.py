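"""Triangular-factor numerics: full Cholesky, rank-1 update/downdate, and
row/column insertion/deletion.

A :class:`CholeskyFactor` stores the lower-triangular factor ``L`` of a
principal submatrix of a kinship matrix, ``L @ L.T == K[ids][:, ids]``,
together with the ordered sample identifiers ``ids`` naming that submatrix.
The lower-triangular convention (positive diagonal) is used throughout the
package.

All positions accepted by :func:`delete_index` and :func:`insert_index` are
0-based, like everything else in Python; a position ``i`` refers to the i-th
row/column of the factored matrix in its current ordering.

The rank-1 sweeps are plane-rotation based: Givens rotations for the update,
hyperbolic rotations for the downdate with a relative pivot guard.  Insertion
of a row/column at position ``i`` is a triangular solve for the new row, a
square-root pivot, and a rank-1 downdate of the trailing block; deletion is
the mirror image (rank-1 update of the trailing block).  Each costs O(order^2)
floating-point work — no full re-decomposition is ever performed internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.linalg.lapack import dpotrf

__all__ = [
    "CholeskyFactor",
    "FactorizationError",
    "DowndateError",
    "InsertionError",
    "full_cholesky",
    "rank1_update",
    "rank1_downdate",
    "delete_index",
    "insert_index",
    "reset_op_count",
    "op_count",
]

#: relative threshold below which a downdate pivot is declared lost
PIVOT_RTOL = 1e-13


class FactorizationError(ValueError):
    """A symmetric matrix failed to factor (not positive definite).

    ``pivot`` is the 0-based index of the first non-positive pivot.
    """

    def __init__(self, pivot: int, context: str = "cholesky factorization"):
        self.pivot = int(pivot)
        super().__init__(
            f"{context} failed: matrix is not positive definite "
            f"(first failing pivot at index {self.pivot})"
        )


class DowndateError(FactorizationError):
    """K - v v^T lost positive definiteness during a downdate sweep."""

    def __init__(self, pivot: int):
        super().__init__(pivot, context="rank-1 downdate")


class InsertionError(FactorizationError):
    """The matrix augmented with the new row/column is not positive definite."""

    def __init__(self, pivot: int):
        super().__init__(pivot, context="row/column insertion")


# ---------------------------------------------------------------------------
# instrumentation: a cheap tally of vectorised floating-point work, used by
# the complexity-contract tests.  Each sweep adds the length of the slice it
# touched; the tally therefore scales like the true flop count.

_OPS: int = 0


def reset_op_count() -> None:
    global _OPS
    _OPS = 0


def op_count() -> int:
    return _OPS


def _tally(n: int) -> None:
    global _OPS
    _OPS += int(n)


# ---------------------------------------------------------------------------


@dataclass
class CholeskyFactor:
    """Lower-triangular factor of ``K[sample_ids][:, sample_ids]``.

    Attributes
    ----------
    tri:
        ``(order, order)`` dense lower-triangular matrix with strictly
        positive diagonal; entries above the diagonal are exactly zero.
    sample_ids:
        Strictly increasing array of the original sample indices whose
        kinship submatrix this factor decomposes.
    """

    tri: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tri = np.asarray(self.tri, dtype=np.float64)
        if self.tri.ndim != 2 or self.tri.shape[0] != self.tri.shape[1]:
            raise ValueError("tri must be a square matrix")
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.tri.shape[0], dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=np.int64)
        if self.sample_ids.shape != (self.tri.shape[0],):
            raise ValueError("sample_ids length must equal factor order")
        if self.sample_ids.size > 1 and not np.all(np.diff(self.sample_ids) > 0):
            raise ValueError("sample_ids must be strictly increasing")

    @property
    def order(self) -> int:
        return self.tri.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Return ``L @ L.T``, the matrix this factor decomposes."""
        return self.tri @ self.tri.T

    def copy(self) -> "CholeskyFactor":
        return CholeskyFactor(self.tri.copy(), self.sample_ids.copy())


def full_cholesky(K_sub: np.ndarray, sample_ids: np.ndarray | None = None) -> CholeskyFactor:
    """Dense lower-Cholesky factorization of a symmetric positive-definite matrix.

    Raises :class:`FactorizationError` naming the first failing pivot when the
    input is not positive definite.
    """
    K_sub = np.asarray(K_sub, dtype=np.float64)
    if K_sub.ndim != 2 or K_sub.shape[0] != K_sub.shape[1]:
        raise ValueError("K_sub must be square")
    c, info = dpotrf(K_sub, lower=1, clean=1, overwrite_a=0)
    if info > 0:
        raise FactorizationError(pivot=info - 1)
    if info < 0:
        raise ValueError(f"illegal argument {-info} to dpotrf")
    return CholeskyFactor(c, sample_ids)


def _check_vec(L: CholeskyFactor, v: np.ndarray, length: int) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).ravel()
    if v.shape != (length,):
        raise ValueError(f"vector of length {v.size} does not match expected {length}")
    return v


def _update_kernel_py(tri: np.ndarray, v: np.ndarray) -> int:
    n = tri.shape[0]
    for k in range(n):
        d = tri[k, k]
        r = np.hypot(d, v[k])
        c = r / d
        s = v[k] / d
        tri[k, k] = r
        if k + 1 < n:
            col = tri[k + 1 :, k]
            col += s * v[k + 1 :]
            col /= c
            v[k + 1 :] = c * v[k + 1 :] - s * col
    return -1


def _downdate_kernel_py(tri: np.ndarray, v: np.ndarray, rtol: float) -> int:
    n = tri.shape[0]
    for k in range(n):
        d = tri[k, k]
        a = v[k] / d
        rho2 = 1.0 - a * a
        if rho2 <= rtol:
            return k
        c = np.sqrt(rho2)
        tri[k, k] = d * c
        if k + 1 < n:
            col = tri[k + 1 :, k]
            col -= a * v[k + 1 :]
            col /= c
            v[k + 1 :] = c * v[k + 1 :] - a * col
    return -1


try:  # compiled sweeps; the numpy path above is the reference semantics
    from numba import njit as _njit

    @_njit(cache=True)
    def _update_kernel(tri, v):  # pragma: no cover - compiled
        n = tri.shape[0]
        for k in range(n):
            d = tri[k, k]
            vk = v[k]
            r = np.hypot(d, vk)
            c = r / d
            s = vk / d
            tri[k, k] = r
            for row in range(k + 1, n):
                t = (tri[row, k] + s * v[row]) / c
                v[row] = c * v[row] - s * t
                tri[row, k] = t
        return -1

    @_njit(cache=True)
    def _downdate_kernel(tri, v, rtol):  # pragma: no cover - compiled
        n = tri.shape[0]
        for k in range(n):
            d = tri[k, k]
            a = v[k] / d
            rho2 = 1.0 - a * a
            if rho2 <= rtol:
                return k
            c = np.sqrt(rho2)
            tri[k, k] = d * c
            for row in range(k + 1, n):
                t = (tri[row, k] - a * v[row]) / c
                v[row] = c * v[row] - a * t
                tri[row, k] = t
        return -1

except ImportError:  # pragma: no cover
    _update_kernel = _update_kernel_py

    def _downdate_kernel(tri, v, rtol):
        return _downdate_kernel_py(tri, v, rtol)


def _update_sweep(tri: np.ndarray, v: np.ndarray) -> None:
    """In-place Givens sweep: tri <- factor of tri @ tri.T + v v^T. Destroys v."""
    n = tri.shape[0]
    _update_kernel(tri, v)
    _tally(3 * n * (n - 1) // 2)


def _downdate_sweep(tri: np.ndarray, v: np.ndarray, err: type = DowndateError) -> None:
    """In-place hyperbolic sweep: tri <- factor of tri @ tri.T - v v^T.

    Raises ``err(pivot=k)`` when positive definiteness is lost at pivot ``k``
    (relative guard 1 - (v_k/d_k)^2 <= PIVOT_RTOL).
    """
    n = tri.shape[0]
    pivot = _downdate_kernel(tri, v, PIVOT_RTOL)
    _tally(3 * n * (n - 1) // 2)
    if pivot >= 0:
        raise err(int(pivot))


def rank1_update(L: CholeskyFactor, v: np.ndarray) -> CholeskyFactor:
    """Factor of ``L L^T + v v^T`` in O(order^2) time."""
    v = _check_vec(L, v, L.order)
    tri = L.tri.copy()
    _update_sweep(tri, v.copy())
    return CholeskyFactor(tri, L.sample_ids.copy())


def rank1_downdate(L: CholeskyFactor, v: np.ndarray) -> CholeskyFactor:
    """Factor of ``L L^T - v v^T`` in O(order^2) time.

    Raises :class:`DowndateError` if the downdated matrix is not positive
    definite (to within the pivot guard).
    """
    v = _check_vec(L, v, L.order)
    tri = L.tri.copy()
    _downdate_sweep(tri, v.copy())
    return CholeskyFactor(tri, L.sample_ids.copy())


def delete_index(L: CholeskyFactor, i: int) -> CholeskyFactor:
    """Factor of the matrix with row/column ``i`` (0-based) removed.

    The leading block is reused untouched and the trailing block receives a
    rank-1 update with the deleted column, so the cost is O((order - i)^2).
    """
    n = L.order
    if n < 2:
        raise ValueError("cannot delete from a factor of order < 2")
    if not 0 <= i < n:
        raise ValueError(f"position {i} out of range for order {n}")
    tri = L.tri
    new = np.zeros((n - 1, n - 1))
    new[:i, :i] = tri[:i, :i]
    new[i:, :i] = tri[i + 1 :, :i]
    new[i:, i:] = tri[i + 1 :, i + 1 :]
    _update_sweep(new[i:, i:], tri[i + 1 :, i].copy())
    ids = np.delete(L.sample_ids, i)
    return CholeskyFactor(new, ids)


def insert_index(L: CholeskyFactor, i: int, v: np.ndarray, sample_id: int) -> CholeskyFactor:
    """Factor of the matrix with a new row/column spliced in at position ``i``.

    ``v`` has length ``order + 1`` and is laid out in the post-insertion
    coordinate system: ``v[i]`` is the new diagonal entry and the remaining
    entries are the covariances between the new sample and the existing ones.
    ``sample_id`` is spliced into ``sample_ids`` at position ``i``.

    Raises :class:`InsertionError` when the augmented matrix is not positive
    definite (non-positive new pivot, or trailing downdate failure).
    """
    n = L.order
    if not 0 <= i <= n:
        raise ValueError(f"position {i} out of range for insertion into order {n}")
    v = _check_vec(L, v, n + 1)
    tri = L.tri
    new = np.zeros((n + 1, n + 1))
    new[:i, :i] = tri[:i, :i]
    # new row i: solve L11 a^T = v[:i]
    if i > 0:
        a = solve_triangular(tri[:i, :i], v[:i], lower=True)
        _tally(i * i)
    else:
        a = np.zeros(0)
    piv2 = v[i] - a @ a
    if piv2 <= PIVOT_RTOL * max(v[i], 1.0):
        raise InsertionError(i)
    d = np.sqrt(piv2)
    new[i, :i] = a
    new[i, i] = d
    if i < n:
        L31 = tri[i:, :i]
        c = (v[i + 1 :] - L31 @ a) / d
        _tally((n - i) * (i + 1))
        new[i + 1 :, :i] = L31
        new[i + 1 :, i] = c
        new[i + 1 :, i + 1 :] = tri[i:, i:]
        try:
            _downdate_sweep(new[i + 1 :, i + 1 :], c.copy(), err=InsertionError)
        except InsertionError as exc:
            raise InsertionError(i + 1 + exc.pivot) from None
    ids = np.insert(L.sample_ids, i, int(sample_id))
    return CholeskyFactor(new, ids)
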