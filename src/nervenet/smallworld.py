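"""Geodesics, characteristic path length, clustering, small-world-ness, and
closeness centralities on binary networks.

Path lengths use unweighted breadth-first distances.  Characteristic path
length requires a (strongly) connected component; closeness averages only
over reachable nodes.  Small-world-ness compares clustering and path length
against a degree-matched rewired ensemble: S = (C/C_rand)/(L/L_rand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import shortest_path

from . import null_models
from .components import giant_component
from .null_models import NullEnsembleSpec
from .wiring import AdjacencyNetwork

__all__ = [
    "PathStats",
    "SmallWorldReport",
    "path_stats",
    "clustering",
    "small_world_ness",
    "closeness_centralities",
]


class DisconnectedComponentError(ValueError):
    """Characteristic path length diverges on a disconnected component."""


@dataclass
class PathStats:
    names: list[str]
    distances: np.ndarray           # integer matrix, np.inf for unreachable
    characteristic_length: float    # mean over ordered pairs i != j
    histogram: dict[int, int]       # distance -> number of ordered pairs


@dataclass
class SmallWorldReport:
    L: float
    C: float
    L_rand: float
    L_rand_sd: float
    C_rand: float
    C_rand_sd: float
    S: float
    n_samples: int


def _bfs_distances(net: AdjacencyNetwork) -> np.ndarray:
    A = sparse.csr_matrix(net.binary())
    return shortest_path(A, method="D", directed=net.directed, unweighted=True)


def path_stats(net: AdjacencyNetwork, component: list[str] | None = None) -> PathStats:
    """Breadth-first geodesic distances and the characteristic path length.

    The network (restricted to ``component`` when given) must be connected —
    strongly connected if directed — otherwise the mean diverges and an
    error names an unreachable pair.
    """
    sub = net.subnetwork(component) if component is not None else net
    d = _bfs_distances(sub)
    n = sub.n
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        if np.any(np.isinf(d[off])):
            i, j = np.argwhere(np.isinf(d) & off)[0]
            raise DisconnectedComponentError(
                f"no path from {sub.names[i]} to {sub.names[j]}: "
                "characteristic path length diverges; restrict to a connected component"
            )
        L = float(d[off].mean())
        vals, counts = np.unique(d[off].astype(int), return_counts=True)
        hist = {int(v): int(c) for v, c in zip(vals, counts)}
    else:
        L = 0.0
        hist = {}
    return PathStats(names=list(sub.names), distances=d, characteristic_length=L, histogram=hist)


def clustering(net: AdjacencyNetwork, mode: str = "undirected") -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean.

    ``undirected``: C_i = 2 E_i / (n_i (n_i - 1)) with E_i the number of
    connections among the n_i neighbours of i.  ``out``: the density of
    directed connections among out-neighbours, E_i / (n_i (n_i - 1)) over
    ordered slots.  C_i = 0 when n_i <= 1.
    """
    B = net.binary()
    n = net.n
    C = np.zeros(n)
    if mode == "undirected":
        Bu = np.maximum(B, B.T) if net.directed else B
        for i in range(n):
            nbrs = np.flatnonzero(Bu[i])
            k = len(nbrs)
            if k > 1:
                sub = Bu[np.ix_(nbrs, nbrs)]
                C[i] = sub.sum() / (k * (k - 1))  # sum counts both triangle ends
    elif mode == "out":
        if not net.directed:
            raise ValueError("mode 'out' requires a directed network")
        for i in range(n):
            nbrs = np.flatnonzero(B[i])
            k = len(nbrs)
            if k > 1:
                sub = B[np.ix_(nbrs, nbrs)]
                C[i] = sub.sum() / (k * (k - 1))
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    return C, float(C.mean()) if n else 0.0


def small_world_ness(
    net: AdjacencyNetwork,
    null_spec: NullEnsembleSpec | None = None,
) -> SmallWorldReport:
    """S = (C/C_rand)/(L/L_rand) against a degree-matched rewired ensemble.

    The input is binarized and restricted to its giant (strongly) connected
    component; ensemble statistics are computed on each null sample's own
    giant component.
    """
    if null_spec is None:
        null_spec = NullEnsembleSpec(
            kind="directed_degree_reciprocity_preserving" if net.directed else "degree_preserving",
            n_samples=100,
        )
    g = giant_component(net.binarized())
    mode = "out" if g.directed else "undirected"
    L = path_stats(g).characteristic_length
    _, C = clustering(g, mode)

    Ls, Cs = [], []
    for sample in null_models.ensemble(g, null_spec):
        gs = giant_component(sample)
        Ls.append(path_stats(gs).characteristic_length)
        Cs.append(clustering(gs, mode)[1])
    L_rand, C_rand = float(np.mean(Ls)), float(np.mean(Cs))
    if C_rand == 0:
        S = math.inf
    else:
        S = (C / C_rand) / (L / L_rand)
    return SmallWorldReport(
        L=L,
        C=C,
        L_rand=L_rand,
        L_rand_sd=float(np.std(Ls)),
        C_rand=C_rand,
        C_rand_sd=float(np.std(Cs)),
        S=float(S),
        n_samples=null_spec.n_samples,
    )


def closeness_centralities(net: AdjacencyNetwork, mode: str = "undirected") -> np.ndarray:
    """Normalized closeness centrality: inverse mean geodesic distance over
    reachable nodes.  ``in`` averages distances from others to the node,
    ``out`` from the node to others; nodes reaching nothing get 0."""
    if mode not in ("undirected", "in", "out"):
        raise ValueError(f"unknown closeness mode {mode!r}")
    if mode in ("in", "out") and not net.directed:
        raise ValueError(f"mode {mode!r} requires a directed network")
    d = _bfs_distances(net)
    if mode == "in":
        d = d.T  # row i now holds distances from all others *to* i
    n = net.n
    out = np.zeros(n)
    for i in range(n):
        row = np.delete(d[i], i)
        reachable = row[np.isfinite(row)]
        if len(reachable):
            out[i] = 1.0 / reachable.mean()
    return out
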