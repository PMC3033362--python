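"""Induced-subgraph censuses and significance against constrained nulls.

Subgraph classes are isomorphism classes of labeled (di)graphs on 2-4
vertices, canonically ordered by edge count, then degree sequence, then
canonical bitmask.  Undirected triples fall into 4 classes and quadruples
into 11; directed pairs into 3 and directed triples into 16 (the triad
census).  Large undirected quadruple censuses enumerate connected subgraphs
(ESU) and recover the disconnected classes from incidence identities;
a brute-force subset enumeration is retained for small networks.

Significance uses one-sided (overrepresentation) plug-in p-values with
step-down min-P (Westfall-Young) multiple-testing adjustment over the full
null-ensemble count matrix.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import null_models
from .null_models import NullEnsembleSpec
from .wiring import AdjacencyNetwork

__all__ = [
    "MotifCensusResult",
    "motif_classes",
    "classify_subgraph",
    "census",
    "census_brute_force",
    "null_census_ensemble",
    "motif_significance",
]


# ---------------------------------------------------------------------------
# Isomorphism-class machinery (bitmask based, sizes 2-4)

def _slots(size: int, directed: bool) -> list[tuple[int, int]]:
    if directed:
        return [(i, j) for i in range(size) for j in range(size) if i != j]
    return [(i, j) for i in range(size) for j in range(i + 1, size)]


@lru_cache(maxsize=None)
def _slot_index(size: int, directed: bool) -> dict[tuple[int, int], int]:
    return {pair: b for b, pair in enumerate(_slots(size, directed))}


def _permute_mask(mask: int, perm: tuple[int, ...], size: int, directed: bool) -> int:
    slots = _slots(size, directed)
    idx = _slot_index(size, directed)
    out = 0
    for b, (i, j) in enumerate(slots):
        if mask >> b & 1:
            a, c = perm[i], perm[j]
            if not directed and a > c:
                a, c = c, a
            out |= 1 << idx[(a, c)]
    return out


@lru_cache(maxsize=None)
def _canonical_table(size: int, directed: bool) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """(canonical mask per labeled mask, class index per labeled mask)."""
    n_bits = len(_slots(size, directed))
    perms = list(itertools.permutations(range(size)))
    canon = [0] * (1 << n_bits)
    for mask in range(1 << n_bits):
        canon[mask] = min(_permute_mask(mask, p, size, directed) for p in perms)
    reps = sorted(set(canon), key=lambda m: _class_sort_key(m, size, directed))
    rep_index = {m: k for k, m in enumerate(reps)}
    classes = tuple(rep_index[c] for c in canon)
    return tuple(canon), classes


def _degree_sequence(mask: int, size: int, directed: bool) -> tuple:
    slots = _slots(size, directed)
    if directed:
        outs, ins = [0] * size, [0] * size
        for b, (i, j) in enumerate(slots):
            if mask >> b & 1:
                outs[i] += 1
                ins[j] += 1
        return tuple(sorted(zip(outs, ins)))
    degs = [0] * size
    for b, (i, j) in enumerate(slots):
        if mask >> b & 1:
            degs[i] += 1
            degs[j] += 1
    return tuple(sorted(degs))


def _class_sort_key(mask: int, size: int, directed: bool):
    return (bin(mask).count("1"), _degree_sequence(mask, size, directed), mask)


@lru_cache(maxsize=None)
def motif_classes(size: int, directed: bool) -> list[int]:
    """Canonical representative masks of all isomorphism classes, in order."""
    canon, _ = _canonical_table(size, directed)
    return sorted(set(canon), key=lambda m: _class_sort_key(m, size, directed))


def n_classes(size: int, directed: bool) -> int:
    return len(motif_classes(size, directed))


def classify_subgraph(sub: np.ndarray, directed: bool) -> int:
    """Class index of a small 0/1 adjacency matrix."""
    size = sub.shape[0]
    mask = 0
    for b, (i, j) in enumerate(_slots(size, directed)):
        if sub[i, j] or (not directed and sub[j, i]):
            mask |= 1 << b
    _, classes = _canonical_table(size, directed)
    return classes[mask]


# ---------------------------------------------------------------------------
# Censuses

_SUPPORTED = {(3, False), (4, False), (2, True), (3, True)}


def _check_supported(size: int, directed: bool) -> None:
    if (size, directed) not in _SUPPORTED:
        raise ValueError(
            f"unsupported census: size={size}, directed={directed}; "
            "supported: undirected 3/4, directed 2/3"
        )


def census_brute_force(net: AdjacencyNetwork, size: int, directed: bool) -> np.ndarray:
    """Counts per class over all C(n, size) vertex subsets (exact, small n)."""
    _check_supported(size, directed)
    B = net.binary().astype(bool)
    if directed and not net.directed:
        raise ValueError("directed census requires a directed network")
    if not directed and net.directed:
        B = B | B.T
    n = net.n
    counts = np.zeros(n_classes(size, directed), dtype=np.int64)
    _, classes = _canonical_table(size, directed)
    slots = _slots(size, directed)
    for subset in itertools.combinations(range(n), size):
        mask = 0
        for b, (i, j) in enumerate(slots):
            if B[subset[i], subset[j]]:
                mask |= 1 << b
        counts[classes[mask]] += 1
    return counts


def _triangles_per_graph(B: np.ndarray) -> int:
    return int(np.round(np.trace(np.linalg.matrix_power(B.astype(float), 3)) / 6))


def _census_undirected3(B: np.ndarray) -> np.ndarray:
    n = B.shape[0]
    deg = B.sum(axis=1)
    E = int(B.sum() // 2)
    T = _triangles_per_graph(B)
    P2 = int(sum(d * (d - 1) // 2 for d in deg)) - 3 * T  # exactly-two-edge triples
    one = E * (n - 2) - 2 * P2 - 3 * T
    empty = math.comb(n, 3) - one - P2 - T
    return np.array([empty, one, P2, T], dtype=np.int64)


def _esu_connected4(B: np.ndarray) -> dict[int, int]:
    """Enumerate connected 4-vertex induced subgraphs (ESU), keyed by class."""
    n = B.shape[0]
    adj = [set(np.flatnonzero(B[i]).tolist()) for i in range(n)]
    _, classes = _canonical_table(4, False)
    slots = _slots(4, False)
    counts: dict[int, int] = {}

    def record(sub: tuple[int, ...]) -> None:
        mask = 0
        for b, (i, j) in enumerate(slots):
            if sub[j] in adj[sub[i]]:
                mask |= 1 << b
        cls = classes[mask]
        counts[cls] = counts.get(cls, 0) + 1

    def extend(sub: list[int], ext: set[int], v: int) -> None:
        if len(sub) == 4:
            record(tuple(sub))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            nbrs = {u for u in adj[w] if u > v and u not in sub}
            excl = nbrs - set().union(*(adj[s] for s in sub)) - ext
            extend(sub + [w], ext | excl, v)

    for v in range(n):
        extend([v], {u for u in adj[v] if u > v}, v)
    return counts


def _pattern(mask: int) -> tuple[int, int, int, int]:
    """(edges, 2-paths, triangles, disjoint-edge-pairs) of a 4-vertex class."""
    slots = _slots(4, False)
    B = np.zeros((4, 4), dtype=bool)
    for b, (i, j) in enumerate(slots):
        if mask >> b & 1:
            B[i, j] = B[j, i] = True
    deg = B.sum(axis=1)
    e = int(B.sum() // 2)
    tr = _triangles_per_graph(B)
    shared = int(sum(d * (d - 1) // 2 for d in deg))
    p2 = shared - 3 * tr
    dp = math.comb(e, 2) - shared
    return e, p2 + 3 * tr, tr, dp  # p2 here counts all adjacent edge pairs


def _census_undirected4(B: np.ndarray) -> np.ndarray:
    """Scalable 4-node census: ESU for connected classes, incidence
    identities for the five disconnected ones."""
    n = B.shape[0]
    reps = motif_classes(4, False)
    counts = np.zeros(len(reps), dtype=np.int64)
    conn_counts = _esu_connected4(B)
    for cls, c in conn_counts.items():
        counts[cls] = c

    deg = B.sum(axis=1)
    E = int(B.sum() // 2)
    T = _triangles_per_graph(B)
    P2_all = int(sum(d * (d - 1) // 2 for d in deg))        # adjacent edge pairs
    DP = math.comb(E, 2) - P2_all                           # disjoint edge pairs

    patterns = [_pattern(m) for m in reps]
    # identify disconnected classes by their patterns
    def find(e, p2a, tr, dp):
        for k, m in enumerate(reps):
            if patterns[k] == (e, p2a, tr, dp) and k not in conn_counts:
                return k
        raise AssertionError("disconnected class pattern not found")

    k_empty = find(0, 0, 0, 0)
    k_one = find(1, 0, 0, 0)
    k_2k2 = find(2, 0, 0, 1)
    k_p3 = find(2, 1, 0, 0)
    k_tri = find(3, 3, 1, 0)

    conn = list(conn_counts.items())
    counts[k_tri] = T * (n - 3) - sum(patterns[k][2] * c for k, c in conn)
    counts[k_p3] = (
        P2_all * (n - 3)
        - sum(patterns[k][1] * c for k, c in conn)
        - 3 * counts[k_tri]
    )
    counts[k_2k2] = DP - sum(patterns[k][3] * c for k, c in conn)
    counts[k_one] = (
        E * math.comb(n - 2, 2)
        - sum(patterns[k][0] * c for k, c in conn)
        - 3 * counts[k_tri]
        - 2 * counts[k_p3]
        - 2 * counts[k_2k2]
    )
    counts[k_empty] = math.comb(n, 4) - counts.sum() + counts[k_empty]
    return counts


def _census_directed2(B: np.ndarray) -> np.ndarray:
    n = B.shape[0]
    mutual = int(np.logical_and(B, B.T).sum() // 2)
    uni = int(B.sum()) - 2 * mutual
    empty = math.comb(n, 2) - uni - mutual
    return np.array([empty, uni, mutual], dtype=np.int64)


_TRIAD_ORDER = None


def _census_directed3(B: np.ndarray, names: list[str]) -> np.ndarray:
    """Triad census via networkx, remapped to the canonical class order."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(B.shape[0]))
    g.add_edges_from(zip(*np.nonzero(B)))
    tc = nx.triadic_census(g)
    counts = np.zeros(n_classes(3, True), dtype=np.int64)
    for name, c in tc.items():
        rep = nx.triad_graph(name)
        sub = np.zeros((3, 3))
        order = {v: k for k, v in enumerate(rep.nodes())}
        for u, v in rep.edges():
            sub[order[u], order[v]] = 1
        counts[classify_subgraph(sub, True)] += c
    return counts


def census(
    net: AdjacencyNetwork, size: int, directed: bool, brute_threshold: int = 40
) -> np.ndarray:
    """Counts of induced subgraphs per isomorphism class (all subsets,
    including disconnected and empty classes)."""
    _check_supported(size, directed)
    if directed and not net.directed:
        raise ValueError("directed census requires a directed network")
    B = net.binary().astype(bool)
    if not directed and net.directed:
        B = B | B.T
    if net.n <= brute_threshold:
        return census_brute_force(net, size, directed)
    if (size, directed) == (3, False):
        return _census_undirected3(B)
    if (size, directed) == (4, False):
        return _census_undirected4(B)
    if (size, directed) == (2, True):
        return _census_directed2(B)
    return _census_directed3(B, net.names)


# ---------------------------------------------------------------------------
# Null ensembles and significance

@dataclass
class MotifCensusResult:
    size: int
    directed: bool
    class_masks: list[int]
    class_counts: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    ratio: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    n_samples: int


def null_census_ensemble(
    net: AdjacencyNetwork, spec: NullEnsembleSpec, size: int, directed: bool
) -> np.ndarray:
    """Census of every null-ensemble sample: (n_samples x n_classes) matrix."""
    _check_supported(size, directed)
    rows = [
        census(sample, size, directed)
        for sample in null_models.ensemble(net.binarized(), spec)
    ]
    return np.array(rows, dtype=np.int64)


def motif_significance(
    observed: np.ndarray, ensemble_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided plug-in p-values with step-down min-P adjustment.

    p_raw(c) = (1 + #{samples with count >= observed_c}) / (R + 1).  The
    adjusted p of the most extreme class is the fraction of ensemble samples
    whose minimum plug-in p over in-play classes is <= its p_raw, proceeding
    step-down with enforced monotonicity.
    """
    X = np.asarray(ensemble_counts, dtype=float)
    if X.size == 0:
        raise ValueError("empty ensemble")
    R, K = X.shape
    if R < 100:
        warnings.warn(f"only {R} ensemble samples; adjusted p-values are unstable")
    o = np.asarray(observed, dtype=float)
    p_raw = (1 + (X >= o[np.newaxis, :]).sum(axis=0)) / (R + 1)
    # plug-in p of each sample's own count against the ensemble
    sample_p = np.empty_like(X)
    for c in range(K):
        col = X[:, c]
        order = np.sort(col)
        # count of col >= value, via searchsorted on the sorted column
        sample_p[:, c] = (1 + (R - np.searchsorted(order, col, side="left"))) / (R + 1)
    order_cls = np.argsort(p_raw, kind="stable")
    p_adj = np.empty(K)
    prev = 0.0
    for rank, c in enumerate(order_cls):
        play = order_cls[rank:]
        minp = sample_p[:, play].min(axis=1)
        q = (1 + (minp <= p_raw[c]).sum()) / (R + 1)
        prev = max(prev, q)
        p_adj[c] = prev
    return p_raw, p_adj


def motif_analysis(
    net: AdjacencyNetwork,
    size: int,
    directed: bool,
    spec: NullEnsembleSpec,
) -> MotifCensusResult:
    """Census + null ensemble + significance in one call."""
    observed = census(net, size, directed)
    X = null_census_ensemble(net, spec, size, directed)
    null_mean = X.mean(axis=0)
    null_sd = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(null_mean > 0, observed / null_mean, np.inf)
        ratio = np.where((null_mean == 0) & (observed == 0), 1.0, ratio)
    p_raw, p_adj = motif_significance(observed, X)
    return MotifCensusResult(
        size=size,
        directed=directed,
        class_masks=motif_classes(size, directed),
        class_counts=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        ratio=ratio,
        p_raw=p_raw,
        p_adjusted=p_adj,
        n_samples=X.shape[0],
    )
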