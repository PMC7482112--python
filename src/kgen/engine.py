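"""Execution of the spanning-tree propagation and whitening solves.

One full O(n^3) Cholesky decomposition is performed at the root phenotype;
every other phenotype's factor is derived from its tree parent by a merged
ascending scan over sample indices, deleting samples observed only in the
source and inserting samples observed only in the target (each an O(n^2)
rank-1 modification).  An edge whose weight exceeds the short-circuit
threshold is instead handled by a fresh full decomposition of the target
submatrix — cheaper once the modification count approaches n.

Factors can be large (d phenotypes times n^2/2 doubles), so completed factors
live in a :class:`FactorStore`, an LRU cache that spills evicted factors to
disk and reloads them bit-identically on demand.  The phenotype *values* are
never read by the propagation — only the missingness pattern matters;
whitening (forward substitution L^-1 y) is a separate step.
"""

from __future__ import annotations

import hashlib
import json
import time
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular

from . import cholmod
from .cholmod import CholeskyFactor, full_cholesky
from .kinship import KinshipMatrix, PhenotypeMatrix
from .planner import SpanningPlan, plan_propagation

__all__ = [
    "FactorStore",
    "EdgeRecord",
    "KgenCounters",
    "KgenResult",
    "propagate_edge",
    "run_kgen",
    "run_naive",
    "whiten",
    "max_entrywise_diff",
]


def _pack_tril(tri: np.ndarray) -> bytes:
    """Row-major packed lower triangle as little-endian float64 bytes."""
    n = tri.shape[0]
    idx = np.tril_indices(n)
    return np.ascontiguousarray(tri[idx], dtype="<f8").tobytes()


def _unpack_tril(data: bytes, order: int) -> np.ndarray:
    flat = np.frombuffer(data, dtype="<f8")
    tri = np.zeros((order, order))
    tri[np.tril_indices(order)] = flat
    return tri


class FactorStore:
    """Bounded-memory map phenotype index -> CholeskyFactor with disk spill.

    At most ``capacity`` factors stay resident; least-recently-used factors
    are evicted to ``spill_dir`` as packed lower triangles (little-endian
    float64) with a JSON sidecar carrying the order, sample ids and a sha256
    checksum.  Retrieval returns a factor bit-identical to what was stored.
    With ``capacity=None`` everything stays in memory.
    """

    def __init__(self, capacity: int | None = None, spill_dir: str | Path | None = None):
        if capacity is not None and capacity < 1:
            raise ValueError("capacity must be >= 1 (or None for unbounded)")
        if capacity is not None and spill_dir is None:
            raise ValueError("a bounded store needs a spill_dir")
        self.capacity = capacity
        self.spill_dir = Path(spill_dir) if spill_dir is not None else None
        self._resident: OrderedDict[int, CholeskyFactor] = OrderedDict()
        self._spilled: set[int] = set()
        if self.spill_dir is not None:
            self.spill_dir.mkdir(parents=True, exist_ok=True)

    def __contains__(self, j: int) -> bool:
        return j in self._resident or j in self._spilled

    def keys(self) -> list[int]:
        return sorted(set(self._resident) | self._spilled)

    def _paths(self, j: int) -> tuple[Path, Path]:
        assert self.spill_dir is not None
        base = self.spill_dir / f"factor_{j:05d}"
        return base.with_suffix(".bin"), base.with_suffix(".json")

    def _spill(self, j: int, factor: CholeskyFactor) -> None:
        bin_path, meta_path = self._paths(j)
        data = _pack_tril(factor.tri)
        bin_path.write_bytes(data)
        meta_path.write_text(
            json.dumps(
                {
                    "order": factor.order,
                    "sample_ids": factor.sample_ids.tolist(),
                    "sha256": hashlib.sha256(data).hexdigest(),
                }
            )
        )
        self._spilled.add(j)

    def _load(self, j: int) -> CholeskyFactor:
        bin_path, meta_path = self._paths(j)
        meta = json.loads(meta_path.read_text())
        data = bin_path.read_bytes()
        digest = hashlib.sha256(data).hexdigest()
        if digest != meta["sha256"]:
            raise IOError(f"checksum mismatch reading spilled factor {j}")
        tri = _unpack_tril(data, int(meta["order"]))
        return CholeskyFactor(tri, np.asarray(meta["sample_ids"], dtype=np.int64))

    def put(self, j: int, factor: CholeskyFactor) -> None:
        self._resident[j] = factor
        self._resident.move_to_end(j)
        if self.capacity is not None:
            while len(self._resident) > self.capacity:
                old_j, old_factor = self._resident.popitem(last=False)
                self._spill(old_j, old_factor)

    def get(self, j: int) -> CholeskyFactor:
        if j in self._resident:
            self._resident.move_to_end(j)
            return self._resident[j]
        if j in self._spilled:
            factor = self._load(j)
            self.put(j, factor)
            return factor
        raise KeyError(f"no factor stored for phenotype {j}")

    def attach_existing(self, indices) -> None:
        """Register factors already present in ``spill_dir`` (e.g. a factor
        directory written by a previous run) as loadable."""
        if self.spill_dir is None:
            raise ValueError("attach_existing requires a spill_dir")
        for j in indices:
            bin_path, meta_path = self._paths(int(j))
            if not (bin_path.exists() and meta_path.exists()):
                raise FileNotFoundError(f"no spilled factor for phenotype {j}")
            self._spilled.add(int(j))

    def flush(self) -> None:
        """Spill every resident factor to disk (requires a spill_dir)."""
        if self.spill_dir is None:
            raise ValueError("cannot flush a store without a spill_dir")
        for j, factor in self._resident.items():
            self._spill(j, factor)


@dataclass
class EdgeRecord:
    """What happened on one plan edge."""

    source: int
    target: int
    weight: int
    inserts: int = 0
    deletes: int = 0
    short_circuited: bool = False


@dataclass
class KgenCounters:
    """Aggregate operation counts for a propagation run."""

    full_decompositions: int = 0
    inserts: int = 0
    deletes: int = 0
    short_circuits: int = 0
    edges: list[EdgeRecord] = field(default_factory=list)

    @property
    def total_modifications(self) -> int:
        return self.inserts + self.deletes

    def to_dict(self) -> dict:
        return {
            "full_decompositions": self.full_decompositions,
            "inserts": self.inserts,
            "deletes": self.deletes,
            "short_circuits": self.short_circuits,
            "edges": [vars(e) for e in self.edges],
        }


@dataclass
class KgenResult:
    """Per-phenotype Cholesky factors plus the plan and counters behind them."""

    store: FactorStore
    plan: SpanningPlan
    counters: KgenCounters
    obs_sets: list[np.ndarray]
    cpu_time: float = 0.0

    @property
    def n_phenotypes(self) -> int:
        return len(self.obs_sets)

    def factor(self, j: int) -> CholeskyFactor:
        return self.store.get(j)


def propagate_edge(
    source_factor: CholeskyFactor,
    target_obs: np.ndarray,
    K: KinshipMatrix,
) -> tuple[CholeskyFactor, int, int]:
    """Turn the factor of K[source_obs] into the factor of K[target_obs].

    A single ascending scan over original sample indices keeps a cursor into
    the evolving factor: samples in both observation sets advance the cursor,
    samples only in the source are deleted at the cursor, and samples only in
    the target are inserted at the cursor with the kinship column restricted
    to the post-insertion sample set.  The scan ends with ``sample_ids``
    exactly equal to ``target_obs``.

    Returns ``(factor, n_inserts, n_deletes)``.
    """
    target_obs = np.asarray(target_obs, dtype=np.int64)
    source_obs = source_factor.sample_ids
    L = source_factor
    n_ins = n_del = 0
    k = 0
    src_iter = iter(source_obs.tolist())
    tgt_iter = iter(target_obs.tolist())
    s = next(src_iter, None)
    t = next(tgt_iter, None)
    while s is not None or t is not None:
        if s is not None and (t is None or s < t):
            # observed only in the source: remove its row/column
            L = cholmod.delete_index(L, k)
            n_del += 1
            s = next(src_iter, None)
        elif t is not None and (s is None or t < s):
            # observed only in the target: splice in its kinship column
            new_ids = np.insert(L.sample_ids, k, t)
            v = K.values[new_ids, t]
            L = cholmod.insert_index(L, k, v, t)
            n_ins += 1
            k += 1
            t = next(tgt_iter, None)
        else:  # s == t, present in both
            k += 1
            s = next(src_iter, None)
            t = next(tgt_iter, None)
    if not np.array_equal(L.sample_ids, target_obs):  # pragma: no cover
        raise AssertionError("propagation did not reach the target observation set")
    return L, n_ins, n_del


def run_kgen(
    K: KinshipMatrix,
    pheno: PhenotypeMatrix,
    short_circuit_threshold: float = 100,
    root_mode: str = "min-obs",
    store: FactorStore | None = None,
) -> KgenResult:
    """Factor K[obs(j)] for every phenotype j via spanning-tree propagation.

    One full decomposition at the root phenotype, then per-edge propagation in
    breadth-first plan order.  Any edge needing more than
    ``short_circuit_threshold`` insert/delete modifications (strict
    comparison) is short-circuited: the target submatrix is decomposed from
    scratch instead.  ``threshold=0`` therefore degenerates to the naive
    method; ``threshold=inf`` never short-circuits.
    """
    pheno.require_no_empty_columns()
    if K.n_samples != pheno.n_samples:
        raise ValueError("kinship and phenotype matrices disagree on sample count")
    if store is None:
        store = FactorStore()
    t0 = time.process_time()
    plan = plan_propagation(pheno, root_mode=root_mode)
    obs_sets = pheno.obs_sets
    counters = KgenCounters()

    root_obs = obs_sets[plan.root]
    store.put(plan.root, full_cholesky(K.submatrix(root_obs), root_obs))
    counters.full_decompositions += 1

    for (src, tgt), weight in zip(plan.edges, plan.edge_weights):
        rec = EdgeRecord(source=src, target=tgt, weight=weight)
        if weight > short_circuit_threshold:
            tgt_obs = obs_sets[tgt]
            store.put(tgt, full_cholesky(K.submatrix(tgt_obs), tgt_obs))
            counters.full_decompositions += 1
            counters.short_circuits += 1
            rec.short_circuited = True
        elif weight == 0:
            # identical observation sets: the factor is shared, not copied
            # (factors are immutable by convention)
            store.put(tgt, store.get(src))
        else:
            factor, n_ins, n_del = propagate_edge(store.get(src), obs_sets[tgt], K)
            store.put(tgt, factor)
            counters.inserts += n_ins
            counters.deletes += n_del
            rec.inserts, rec.deletes = n_ins, n_del
        counters.edges.append(rec)

    return KgenResult(
        store=store,
        plan=plan,
        counters=counters,
        obs_sets=obs_sets,
        cpu_time=time.process_time() - t0,
    )


def run_naive(
    K: KinshipMatrix,
    pheno: PhenotypeMatrix,
    store: FactorStore | None = None,
) -> KgenResult:
    """Reference method: one independent full decomposition per phenotype."""
    pheno.require_no_empty_columns()
    if K.n_samples != pheno.n_samples:
        raise ValueError("kinship and phenotype matrices disagree on sample count")
    if store is None:
        store = FactorStore()
    t0 = time.process_time()
    obs_sets = pheno.obs_sets
    counters = KgenCounters()
    for j, obs in enumerate(obs_sets):
        store.put(j, full_cholesky(K.submatrix(obs), obs))
        counters.full_decompositions += 1
    plan = SpanningPlan(root=0, edges=[], edge_weights=[])
    return KgenResult(
        store=store,
        plan=plan,
        counters=counters,
        obs_sets=obs_sets,
        cpu_time=time.process_time() - t0,
    )


def whiten(L: CholeskyFactor, y_obs: np.ndarray) -> np.ndarray:
    """Forward substitution ``x = L^-1 y`` so that ``x.T x = y.T K_j^-1 y``."""
    y_obs = np.asarray(y_obs, dtype=np.float64)
    if y_obs.shape[0] != L.order:
        raise ValueError(
            f"phenotype vector length {y_obs.shape[0]} does not match factor order {L.order}"
        )
    return solve_triangular(L.tri, y_obs, lower=True)


def max_entrywise_diff(a: KgenResult, b: KgenResult) -> float:
    """Max over phenotypes of the max entrywise |L_j^a - L_j^b|.

    Factors are fetched pairwise through the stores, so memory stays bounded
    even when both results spill to disk.  Raises when the two results were
    computed for different observation sets.
    """
    if a.n_phenotypes != b.n_phenotypes:
        raise ValueError("results cover different numbers of phenotypes")
    worst = 0.0
    for j in range(a.n_phenotypes):
        fa, fb = a.factor(j), b.factor(j)
        if not np.array_equal(fa.sample_ids, fb.sample_ids):
            raise ValueError(f"observation sets differ for phenotype {j}")
        worst = max(worst, float(np.abs(fa.tri - fb.tri).max()))
    return worst
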