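"""Connected-component analysis and closed-form random-graph analytics.

Includes the Erdös–Rényi giant-component statistics (Lambert-W fixed point)
and the generating-function machinery for graphs with an arbitrary degree
distribution: giant-component fraction, mean small-component size, and the
expected path length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc
from scipy.special import lambertw

from .wiring import AdjacencyNetwork

__all__ = [
    "ComponentPartition",
    "DegreeDistribution",
    "ErGiantStats",
    "connected_components",
    "giant_component",
    "er_giant_stats",
    "gf_giant_component",
    "gf_expected_path_length",
    "degree_distribution_from_network",
]


@dataclass
class ComponentPartition:
    mode: Literal["undirected", "weak", "strong"]
    components: list[set[str]]  # sorted by decreasing size
    isolated: set[str]

    @property
    def giant(self) -> set[str]:
        return self.components[0] if self.components else set()

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


@dataclass
class DegreeDistribution:
    """Probabilities p_k for k = 0..k_max, summing to 1."""

    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.probabilities = p

    @property
    def ks(self) -> np.ndarray:
        return np.arange(len(self.probabilities))

    @property
    def z1(self) -> float:
        """Mean degree."""
        return float((self.ks * self.probabilities).sum())

    @property
    def z2(self) -> float:
        """Mean number of second neighbours, sum k(k-1) p_k."""
        k = self.ks
        return float((k * (k - 1) * self.probabilities).sum())

    def g0(self, x: float) -> float:
        return float((self.probabilities * x ** self.ks).sum())

    def g1(self, x: float) -> float:
        """Excess-degree generating function G0'(x)/G0'(1)."""
        k = self.ks[1:]
        p = self.probabilities[1:]
        return float((k * p * x ** (k - 1)).sum() / self.z1)


@dataclass
class ErGiantStats:
    mean_size: float
    variance: float
    rho: float


def connected_components(
    net: AdjacencyNetwork, mode: Literal["undirected", "weak", "strong"] = "undirected"
) -> ComponentPartition:
    """Partition neurons into connected components.

    ``strong`` requires mutual reachability respecting directions; ``weak``
    ignores directions; ``undirected`` applies to undirected networks.
    """
    if mode in ("weak", "strong") and not net.directed:
        raise ValueError(f"mode {mode!r} requires a directed network")
    if mode == "undirected" and net.directed:
        raise ValueError("use mode 'weak' or 'strong' on a directed network")
    A = sparse.csr_matrix(net.binary())
    n_comp, labels = _cc(
        A,
        directed=net.directed,
        connection="strong" if mode == "strong" else "weak",
    )
    comps: list[set[str]] = [set() for _ in range(n_comp)]
    for name, lab in zip(net.names, labels):
        comps[lab].add(name)
    comps.sort(key=lambda c: (-len(c), min(c) if c else ""))
    isolated = {next(iter(c)) for c in comps if len(c) == 1}
    return ComponentPartition(mode=mode, components=comps, isolated=isolated)


def giant_component(
    net: AdjacencyNetwork, mode: Literal["undirected", "weak", "strong"] | None = None
) -> AdjacencyNetwork:
    """Restrict a network to its largest component (strong, if directed and
    unspecified mode is resolved to 'strong' for spectral/path comparability)."""
    if mode is None:
        mode = "strong" if net.directed else "undirected"
    part = connected_components(net, mode)
    keep = [nm for nm in net.names if nm in part.giant]
    return net.subnetwork(keep)


def er_giant_stats(n: int, p: float) -> ErGiantStats:
    """Asymptotic mean/variance of the ER giant-component size.

    The giant fraction rho solves rho = 1 - exp(-c rho) with c = p (n-1),
    evaluated through the Lambert-W branch rho = 1 + W(-c e^-c)/c.  Variance
    follows the asymptotic-normality form n rho (1 - rho) / (1 - c(1-rho))^2.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0,1], got {p}")
    c = p * (n - 1)
    if c <= 1:
        return ErGiantStats(mean_size=0.0, variance=0.0, rho=0.0)
    rho = float(1 + np.real(lambertw(-c * np.exp(-c))) / c)
    var = n * rho * (1 - rho) / (1 - c * (1 - rho)) ** 2
    return ErGiantStats(mean_size=n * rho, variance=var, rho=rho)


def gf_giant_component(dist: DegreeDistribution) -> tuple[float, float, float]:
    """Giant component of a configuration-model graph with distribution p_k.

    Returns ``(u, giant_fraction, mean_small_component)`` where ``u`` is the
    smallest non-negative fixed point of u = G1(u), the giant fraction is
    S = 1 - G0(u), and the mean small-component size is the
    generating-function expression 1 + z1 u^2 / ((1 - S)(1 - G1'(u))).
    """
    z1 = dist.z1
    if z1 <= 0:
        raise ValueError("mean degree must be positive")
    # iterate u <- G1(u) from 0; converges to the smallest fixed point
    u = 0.0
    for _ in range(10000):
        nxt = dist.g1(u)
        if abs(nxt - u) < 1e-14:
            u = nxt
            break
        u = nxt
    u = min(max(u, 0.0), 1.0)
    S = 1.0 - dist.g0(u)
    k = dist.ks[2:]
    p = dist.probabilities[2:]
    g1p_u = float((k * (k - 1) * p * u ** (k - 2)).sum() / z1)  # G1'(u)
    if abs(1 - g1p_u) < 1e-12 or S >= 1 - 1e-15:
        mean_small = float("inf") if S < 1 - 1e-15 else 1.0
    else:
        mean_small = 1 + z1 * u**2 / ((1 - S) * (1 - g1p_u))
    return u, S, mean_small


def gf_expected_path_length(dist: DegreeDistribution, n: int) -> float:
    """Expected geodesic distance ln(n/z1)/ln(z2/z1) + 1 for the
    configuration-model ensemble with this degree distribution."""
    z1, z2 = dist.z1, dist.z2
    if z1 <= 0 or z2 <= z1:
        raise ValueError(f"path-length formula requires z2 > z1 > 0 (z1={z1}, z2={z2})")
    return float(np.log(n / z1) / np.log(z2 / z1) + 1)


def degree_distribution_from_network(net: AdjacencyNetwork) -> DegreeDistribution:
    """Empirical degree distribution of an undirected (or symmetrized) network."""
    B = net.binary()
    if net.directed:
        B = np.maximum(B, B.T)
    degrees = B.sum(axis=1).astype(int)
    counts = np.bincount(degrees)
    return DegreeDistribution(counts / counts.sum())
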