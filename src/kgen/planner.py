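"""Propagation planning over phenotype missingness patterns.

Phenotypes form the vertices of a complete weighted graph; the weight between
two phenotypes is the size of the symmetric difference of their observation
sets — exactly the number of rank-1 row/column insertions plus deletions
needed to turn the kinship submatrix factor of one into that of the other.
A minimum spanning tree of this graph, rooted at a chosen phenotype and
enumerated breadth-first, gives the cheapest propagation order: every edge's
source factor is already available (and recently touched) when the edge is
processed.

Kruskal's algorithm with union-find is used for the tree; edges are sorted by
(weight, min vertex, max vertex) so that plans are deterministic under ties.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .kinship import PhenotypeMatrix

__all__ = [
    "MissingnessGraph",
    "SpanningPlan",
    "build_graph",
    "minimum_spanning_tree",
    "choose_root",
    "breadth_first_plan",
    "plan_propagation",
]


@dataclass
class MissingnessGraph:
    """Complete graph on phenotypes; weights = symmetric-difference sizes."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int64)
        d = self.weights.shape[0]
        if self.weights.shape != (d, d):
            raise ValueError("weights must be square")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal weights must be zero")

    @property
    def n_phenotypes(self) -> int:
        return self.weights.shape[0]

    @property
    def max_pairwise_weight(self) -> int:
        """r: the largest modification count between any two phenotypes."""
        d = self.n_phenotypes
        if d < 2:
            return 0
        return int(self.weights[np.triu_indices(d, k=1)].max())


@dataclass
class SpanningPlan:
    """Ordered propagation plan: root, breadth-first oriented edges, weights."""

    root: int
    edges: list[tuple[int, int]]
    edge_weights: list[int] = field(default_factory=list)

    @property
    def total_weight(self) -> int:
        return int(sum(self.edge_weights))

    def to_json(self) -> str:
        return json.dumps(
            {
                "root": self.root,
                "edges": [list(e) for e in self.edges],
                "edge_weights": list(map(int, self.edge_weights)),
                "total_weight": self.total_weight,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SpanningPlan":
        obj = json.loads(text)
        return cls(
            root=int(obj["root"]),
            edges=[tuple(e) for e in obj["edges"]],
            edge_weights=[int(w) for w in obj["edge_weights"]],
        )


def build_graph(pheno: PhenotypeMatrix) -> MissingnessGraph:
    """Pairwise symmetric-difference weights between observation sets.

    With M the boolean observed-mask, |obs(j1) Δ obs(j2)| equals
    #obs(j1) + #obs(j2) - 2 * #(obs(j1) ∩ obs(j2)), computed via one Gram
    product of the mask.
    """
    M = pheno.observed_mask.astype(np.int64)
    counts = M.sum(axis=0)
    both = M.T @ M
    W = counts[:, None] + counts[None, :] - 2 * both
    return MissingnessGraph(W)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def minimum_spanning_tree(graph: MissingnessGraph) -> list[tuple[int, int]]:
    """Kruskal MST of the complete missingness graph.

    Returns d-1 undirected edges (u < v). Deterministic: candidate edges are
    processed in (weight, u, v) lexicographic order.
    """
    d = graph.n_phenotypes
    if d <= 1:
        return []
    iu, iv = np.triu_indices(d, k=1)
    w = graph.weights[iu, iv]
    order = np.lexsort((iv, iu, w))
    uf = _UnionFind(d)
    tree: list[tuple[int, int]] = []
    for idx in order:
        u, v = int(iu[idx]), int(iv[idx])
        if uf.union(u, v):
            tree.append((u, v))
            if len(tree) == d - 1:
                break
    return tree


def choose_root(pheno: PhenotypeMatrix, mode: str = "min-obs") -> int:
    """Root phenotype for the one full decomposition.

    ``"min-obs"`` (default) picks the phenotype with the fewest observed
    samples, minimizing the cubic-cost decomposition; ``"max-obs"`` picks the
    most-observed phenotype.  Ties break to the smallest phenotype index.
    """
    counts = pheno.observed_mask.sum(axis=0)
    if mode == "min-obs":
        return int(np.argmin(counts))
    if mode == "max-obs":
        return int(np.argmax(counts))
    raise ValueError(f"unknown root mode {mode!r}; use 'min-obs' or 'max-obs'")


def breadth_first_plan(
    tree: list[tuple[int, int]],
    root: int,
    graph: MissingnessGraph | None = None,
) -> SpanningPlan:
    """Orient and order tree edges breadth-first from the root.

    Each edge is emitted as (source, target) with the source already reached;
    children of a vertex are visited in ascending target index.  Edge weights
    are attached when the graph is supplied.
    """
    adj: dict[int, list[int]] = {}
    vertices = {root}
    for u, v in tree:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
        vertices.update((u, v))
    if root not in adj and len(vertices) > 1:
        raise ValueError(f"root {root} does not appear in the spanning tree")
    for nbrs in adj.values():
        nbrs.sort()
    edges: list[tuple[int, int]] = []
    seen = {root}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, []):
            if v not in seen:
                seen.add(v)
                edges.append((u, v))
                queue.append(v)
    if seen != vertices:
        raise ValueError("edges do not form a tree spanning all phenotypes")
    weights = (
        [int(graph.weights[u, v]) for u, v in edges] if graph is not None else []
    )
    return SpanningPlan(root=root, edges=edges, edge_weights=weights)


def plan_propagation(pheno: PhenotypeMatrix, root_mode: str = "min-obs") -> SpanningPlan:
    """Full pipeline: graph, MST, root, breadth-first enumeration."""
    graph = build_graph(pheno)
    tree = minimum_spanning_tree(graph)
    root = choose_root(pheno, mode=root_mode)
    return breadth_first_plan(tree, root, graph)
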