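"""Random-network null ensembles: ER sampling and constrained edge rewiring.

Rewiring moves are double-edge swaps that exactly preserve the prescribed
invariants — degree sequences, optionally the global triangle count, and for
directed networks the per-node counts of unidirectional and bidirectional
connections (bidirectional and unidirectional edges are swapped only within
their own pools).  All samplers operate on binary networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

from .wiring import AdjacencyNetwork

__all__ = ["NullEnsembleSpec", "sample_er", "rewire", "ensemble"]

NullKind = Literal[
    "er",
    "degree_preserving",
    "degree_triangle_preserving",
    "directed_degree_reciprocity_preserving",
    "degree_sequence_permutation",
]


@dataclass
class NullEnsembleSpec:
    kind: NullKind = "degree_preserving"
    n_samples: int = 1000
    swaps_per_edge: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


def sample_er(
    n: int, p: float, directed: bool, seed: int | np.random.Generator = 0
) -> AdjacencyNetwork:
    """Erdös–Rényi network: every (ordered or unordered) pair independently
    connected with probability ``p``."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0,1], got {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [f"N{i + 1:03d}" for i in range(n)]
    A = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(A, 0.0)
    if not directed:
        A = np.triu(A)
        A = A + A.T
    return AdjacencyNetwork(names=names, weights=A, directed=directed, quantitation="binary")


def _require_binary(net: AdjacencyNetwork) -> None:
    w = net.weights
    if not np.all((w == 0) | (w == 1)):
        raise ValueError("rewiring requires a binary network; call .binarized() first")


def _undirected_swap_pass(A: np.ndarray, n_attempts: int, rng, preserve_triangles: bool):
    """Attempt double-edge swaps in place on a symmetric 0/1 matrix."""
    n = A.shape[0]
    edges = [(i, j) for i, j in zip(*np.nonzero(np.triu(A))) ]
    if len(edges) < 2:
        return
    if preserve_triangles:
        def edge_triangles(a, b):
            # triangles through edge (a,b) = common neighbours
            return int(np.dot(A[a], A[b]))
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, len(edges), size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,c),(b,d)
        if len({a, b, c, d}) < 4:
            continue
        if A[a, c] or A[b, d]:
            continue
        if preserve_triangles:
            before = edge_triangles(a, b) + edge_triangles(c, d)
            # triangles double-counted when (a,b,c,d) share neighbours, but the
            # swap is accepted only on exact global equality computed after
            A[a, b] = A[b, a] = 0
            A[c, d] = A[d, c] = 0
            after = int(np.dot(A[a], A[c])) + int(np.dot(A[b], A[d]))
            if after != before:
                A[a, b] = A[b, a] = 1
                A[c, d] = A[d, c] = 1
                continue
            A[a, c] = A[c, a] = 1
            A[b, d] = A[d, b] = 1
        else:
            A[a, b] = A[b, a] = 0
            A[c, d] = A[d, c] = 0
            A[a, c] = A[c, a] = 1
            A[b, d] = A[d, b] = 1
        edges[e1] = (min(a, c), max(a, c))
        edges[e2] = (min(b, d), max(b, d))


def _directed_swap_pass(A: np.ndarray, edges: list, n_attempts: int, rng, bidirectional: bool):
    """Swap within one pool (unidirectional or bidirectional edges) in place.

    For the unidirectional pool, (a->b),(c->d) becomes (a->d),(c->b) provided
    no self-loop, no existing edge in either direction is created (which would
    change reciprocity counts).  For the bidirectional pool, the mutual pairs
    {a,b},{c,d} become {a,d},{c,b} under the same constraints.
    """
    if len(edges) < 2:
        return
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, len(edges), size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if bidirectional and rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        # target pairs must be empty in both directions
        if A[a, d] or A[d, a] or A[c, b] or A[b, c]:
            continue
        if bidirectional:
            A[a, b] = A[b, a] = 0
            A[c, d] = A[d, c] = 0
            A[a, d] = A[d, a] = 1
            A[c, b] = A[b, c] = 1
        else:
            A[a, b] = 0
            A[c, d] = 0
            A[a, d] = 1
            A[c, b] = 1
        edges[e1] = (a, d)
        edges[e2] = (c, b)


def rewire(
    net: AdjacencyNetwork,
    kind: NullKind = "degree_preserving",
    swaps_per_edge: int = 100,
    seed: int | np.random.Generator = 0,
) -> AdjacencyNetwork:
    """Sample a random network with the prescribed invariants of ``net``.

    ``degree_preserving`` and ``degree_triangle_preserving`` apply to
    undirected networks; ``directed_degree_reciprocity_preserving`` preserves
    each node's in-/out-degree and its number of unidirectional and
    bidirectional partners.
    """
    _require_binary(net)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = net.weights.copy()

    if kind in ("degree_preserving", "degree_triangle_preserving"):
        if net.directed:
            raise ValueError(f"{kind} rewiring requires an undirected network")
        n_edges = int(np.triu(A).sum())
        _undirected_swap_pass(
            A, swaps_per_edge * max(n_edges, 1), rng,
            preserve_triangles=(kind == "degree_triangle_preserving"),
        )
    elif kind == "directed_degree_reciprocity_preserving":
        if not net.directed:
            raise ValueError("reciprocity-preserving rewiring requires a directed network")
        mutual = np.logical_and(A > 0, A.T > 0)
        uni = np.logical_and(A > 0, A.T == 0)
        bi_edges = [(i, j) for i, j in zip(*np.nonzero(np.triu(mutual)))]
        uni_edges = [(i, j) for i, j in zip(*np.nonzero(uni))]
        _directed_swap_pass(A, uni_edges, swaps_per_edge * max(len(uni_edges), 1), rng, False)
        _directed_swap_pass(A, bi_edges, swaps_per_edge * max(len(bi_edges), 1), rng, True)
    elif kind == "degree_preserving_directed":
        raise ValueError("use 'directed_degree_reciprocity_preserving' for directed nets")
    else:
        raise ValueError(f"unknown rewiring kind {kind!r}")

    return AdjacencyNetwork(
        names=list(net.names), weights=A, directed=net.directed, quantitation="binary"
    )


def ensemble(
    net: AdjacencyNetwork, spec: NullEnsembleSpec
) -> Iterator[AdjacencyNetwork]:
    """Stream ``spec.n_samples`` null networks (bounded memory)."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "er":
        n = net.n
        pairs = n * (n - 1) if net.directed else n * (n - 1) // 2
        p = float((net.binary().sum() if net.directed else np.triu(net.binary()).sum()) / pairs)
        for _ in range(spec.n_samples):
            yield sample_er(n, p, net.directed, rng)
    else:
        for _ in range(spec.n_samples):
            yield rewire(net, spec.kind, spec.swaps_per_edge, rng)
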