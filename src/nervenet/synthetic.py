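"""Synthetic wiring-diagram generator.

Produces diagrams with the statistical structure the analysis pipeline
assumes: a heavy-tailed undirected gap-junction network (configuration model
on power-law degrees), a directed chemical network with heavy-tailed in/out
degrees, stretched-exponential connection multiplicities, a tunable
association between gap and chemical connections, bilateral name pairs, a
GABAergic subset, and a tunable polyadic-contact fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wiring import NeuronRecord, SynapseRecord, WiringDiagram

__all__ = ["SynthParams", "generate_connectome", "worked_fixture",
           "sample_multiplicities", "sample_powerlaw_degrees"]


class DegreeSequenceError(RuntimeError):
    """Configuration-model pairing failed; try a smaller exponent tail or n."""


@dataclass
class SynthParams:
    """Parameters for :func:`generate_connectome`."""

    n_neurons: int = 280
    frac_sensory: float = 0.3
    frac_inter: float = 0.3
    frac_motor: float = 0.4
    gap_degree_exponent: float = 3.0
    chem_degree_exponent: float = 3.0
    mean_gap_connections: float = 3.6   # mean gap degree per neuron
    mean_chem_connections: float = 7.0  # mean chemical out-degree per neuron
    multiplicity_shape: float = 0.7     # stretched-exponential beta
    multiplicity_scale: float = 2.0     # stretched-exponential lambda
    overlap_odds: float = 3.0           # chem odds multiplier on gap pairs
    reciprocity: float = 0.2            # extra prob of a reverse chem edge
    gaba_fraction: float = 0.1
    polyadic_fraction: float = 0.3
    bilateral: bool = True
    degree_cutoff: int | None = None    # max degree draw; default sqrt(n)
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_sensory, self.frac_inter, self.frac_motor)
        if any(not 0 <= f <= 1 for f in fracs) or abs(sum(fracs) - 1) > 1e-9:
            raise ValueError("category fractions must lie in [0,1] and sum to 1")
        if self.gap_degree_exponent <= 1 or self.chem_degree_exponent <= 1:
            raise ValueError("degree exponents must exceed 1")
        if not 0 <= self.gaba_fraction <= 1 or not 0 <= self.polyadic_fraction <= 1:
            raise ValueError("fractions must lie in [0,1]")
        if not 0 <= self.reciprocity <= 1:
            raise ValueError("reciprocity must lie in [0,1]")
        if self.overlap_odds < 0:
            raise ValueError("overlap_odds must be non-negative")
        if self.multiplicity_shape <= 0 or self.multiplicity_scale <= 0:
            raise ValueError("multiplicity parameters must be positive")


def sample_powerlaw_degrees(
    rng: np.random.Generator, n: int, exponent: float, mean_target: float, k_max: int
) -> np.ndarray:
    """Draw i.i.d. degrees with a discrete power-law tail P(k) ~ k^-exponent.

    Degrees are zeta-distributed, truncated at ``k_max``; a zero-inflation /
    thinning mixture tunes the mean toward ``mean_target`` without touching
    the tail exponent.
    """
    ks = np.arange(1, k_max + 1)
    pk = ks.astype(float) ** -exponent
    pk /= pk.sum()
    mean_zeta = (ks * pk).sum()
    deg = rng.choice(ks, size=n, p=pk)
    if mean_target <= mean_zeta:
        keep = rng.random(n) < mean_target / mean_zeta
        deg = np.where(keep, deg, 0)
    else:
        # add Poisson bulk to raise the mean; tail still power-law dominated
        deg = deg + rng.poisson(mean_target - mean_zeta, size=n)
    return deg.astype(int)


def _configuration_model_edges(
    rng: np.random.Generator, degrees: np.ndarray, max_tries: int = 1000
) -> set[tuple[int, int]]:
    """Pair stubs into a simple graph.

    Invalid pairings (self-loops, parallel edges) are rejected and resolved
    by degree-preserving swaps against randomly chosen valid edges; the
    degree sequence is realized exactly.
    """
    degrees = degrees.copy()
    if degrees.sum() % 2 == 1:
        degrees[int(np.argmin(degrees))] += 1  # repair to an even stub count
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    if len(stubs) == 0:
        return set()
    rng.shuffle(stubs)
    edges = [[int(u), int(v)] for u, v in zip(stubs[0::2], stubs[1::2])]

    def key(u, v):
        return (u, v) if u <= v else (v, u)

    counts: dict[tuple[int, int], int] = {}
    for u, v in edges:
        counts[key(u, v)] = counts.get(key(u, v), 0) + 1
    bad = [
        k for k, (u, v) in enumerate(edges)
        if u == v or counts[key(u, v)] > 1
    ]
    attempts = 0
    limit = max_tries * max(len(edges), 1)
    while bad:
        k = bad.pop()
        u, v = edges[k]
        if u != v and counts[key(u, v)] == 1:
            continue  # already repaired by an earlier swap
        attempts += 1
        if attempts > limit:
            raise DegreeSequenceError(
                "could not realize the degree sequence as a simple graph "
                f"after {limit} swap attempts; lower the mean degree or "
                "raise the exponent"
            )
        m = int(rng.integers(0, len(edges)))
        x, y = edges[m]
        if m == k or len({u, v, x, y}) < (3 if u == v else 4):
            bad.append(k)
            continue
        # propose (u,v),(x,y) -> (u,y),(x,v)
        if u == y or x == v or counts.get(key(u, y), 0) or counts.get(key(x, v), 0):
            bad.append(k)
            continue
        for a, b in (edges[k], edges[m]):
            counts[key(a, b)] -= 1
        edges[k] = [u, y]
        edges[m] = [x, v]
        for a, b in (edges[k], edges[m]):
            counts[key(a, b)] = counts.get(key(a, b), 0) + 1
    return {key(u, v) for u, v in edges}


def sample_multiplicities(
    rng: np.random.Generator, n: int, scale: float, shape: float
) -> np.ndarray:
    """Sample the discrete stretched-exponential law
    P(M >= m) = exp(-((m-1)/scale)^shape) for m >= 1, by inversion."""
    u = rng.random(n)
    return 1 + np.floor(scale * (-np.log(u)) ** (1.0 / shape)).astype(int)


def _neuron_table(params: SynthParams, rng: np.random.Generator) -> list[NeuronRecord]:
    n = params.n_neurons
    neurons: list[NeuronRecord] = []
    if params.bilateral:
        n_pairs, n_single = divmod(n, 2)
        classes = [f"N{i + 1:03d}" for i in range(n_pairs + n_single)]
        for i in range(n_pairs):
            for side in ("L", "R"):
                neurons.append(NeuronRecord(f"{classes[i]}{side}", "sensory", False, side, classes[i]))
        for i in range(n_pairs, n_pairs + n_single):
            neurons.append(NeuronRecord(classes[i], "sensory", False, "none", classes[i]))
    else:
        neurons = [
            NeuronRecord(f"N{i + 1:03d}", "sensory", False, "none", f"N{i + 1:03d}")
            for i in range(n)
        ]

    # assign categories by fractions, GABA among inter+motor neurons
    n_s = round(params.frac_sensory * n)
    n_i = round(params.frac_inter * n)
    cats = ["sensory"] * n_s + ["interneuron"] * n_i + ["motor"] * (n - n_s - n_i)
    gaba_pool = [k for k, c in enumerate(cats) if c != "sensory"]
    n_gaba = round(params.gaba_fraction * len(gaba_pool))
    gaba_idx = set(rng.choice(gaba_pool, size=n_gaba, replace=False)) if n_gaba else set()
    return [
        NeuronRecord(nr.name, cats[k], k in gaba_idx, nr.side, nr.neuron_class)
        for k, nr in enumerate(neurons)
    ]


def generate_connectome(params: SynthParams) -> WiringDiagram:
    """Generate a synthetic wiring diagram (deterministic given the seed)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_neurons
    if n == 0:
        return WiringDiagram(neurons=[], records=[])
    neurons = _neuron_table(params, rng)

    # --- gap-junction network: configuration model on power-law degrees
    k_max = params.degree_cutoff or max(2, int(np.sqrt(max(n, 4))))
    gap_deg = sample_powerlaw_degrees(
        rng, n, params.gap_degree_exponent, params.mean_gap_connections, min(k_max, n - 1)
    )
    gap_pairs = _configuration_model_edges(rng, gap_deg) if n > 1 else set()

    # --- chemical network: independent heavy-tailed propensities per neuron,
    #     odds boosted on gap-junction pairs
    base_mean_p = min(params.mean_chem_connections / max(n - 1, 1), 0.9)
    w_out = sample_powerlaw_degrees(rng, n, params.chem_degree_exponent, 1.0, min(k_max, n - 1)) + 1.0
    w_in = sample_powerlaw_degrees(rng, n, params.chem_degree_exponent, 1.0, min(k_max, n - 1)) + 1.0
    W = np.outer(w_out, w_in)
    np.fill_diagonal(W, 0.0)
    P = np.minimum(W * (base_mean_p * (n * (n - 1)) / W.sum()), 0.95) if W.sum() > 0 else W
    if params.overlap_odds != 1.0 and gap_pairs:
        odds = params.overlap_odds
        for i, j in gap_pairs:
            for a, b in ((i, j), (j, i)):
                p = P[a, b]
                P[a, b] = odds * p / (1 - p + odds * p) if p > 0 else 0.0
    chem_mask = rng.random((n, n)) < P
    np.fill_diagonal(chem_mask, False)
    if params.reciprocity > 0:
        # reverse edges drawn independently of gap presence, so reciprocity
        # does not bias the gap/chemical interaction statistics
        rev = chem_mask.T.copy() & (rng.random((n, n)) < params.reciprocity)
        chem_mask |= rev

    records: list[SynapseRecord] = []
    names = [nr.name for nr in neurons]

    gap_list = sorted(gap_pairs)
    gap_mult = sample_multiplicities(
        rng, len(gap_list), params.multiplicity_scale, params.multiplicity_shape
    )
    for (i, j), m in zip(gap_list, gap_mult):
        records.append(SynapseRecord(names[i], names[j], "gap", int(m), 0))
        records.append(SynapseRecord(names[j], names[i], "gap", int(m), 0))

    chem_edges = np.argwhere(chem_mask)
    chem_mult = sample_multiplicities(
        rng, len(chem_edges), params.multiplicity_scale, params.multiplicity_shape
    )
    poly = rng.binomial(chem_mult, params.polyadic_fraction)
    for (i, j), m, q in zip(chem_edges, chem_mult, poly):
        records.append(SynapseRecord(names[i], names[j], "chem", int(m), int(q)))

    return WiringDiagram(neurons=neurons, records=records)


def worked_fixture() -> WiringDiagram:
    """A pinned 12-neuron diagram for documentation and brute-force tests.

    Contains a reciprocal chemical pair (A01L <-> A01R), a chemical cycle,
    gap-junction triangles (B01L-B01R-C01 and the hub around D01), a
    gap/chemical overlapping pair (A01L-A01R), and a GABAergic motor neuron.
    """
    neurons = [
        NeuronRecord("A01L", "sensory", False, "L", "A01"),
        NeuronRecord("A01R", "sensory", False, "R", "A01"),
        NeuronRecord("B01L", "sensory", False, "L", "B01"),
        NeuronRecord("B01R", "sensory", False, "R", "B01"),
        NeuronRecord("C01", "interneuron", False, "none", "C01"),
        NeuronRecord("C02L", "interneuron", False, "L", "C02"),
        NeuronRecord("C02R", "interneuron", False, "R", "C02"),
        NeuronRecord("D01", "interneuron", False, "none", "D01"),
        NeuronRecord("E01L", "motor", True, "L", "E01"),
        NeuronRecord("E01R", "motor", False, "R", "E01"),
        NeuronRecord("E02", "motor", False, "none", "E02"),
        NeuronRecord("F01", "motor", False, "none", "F01"),
    ]

    def gap(a, b, m):
        return [SynapseRecord(a, b, "gap", m, 0), SynapseRecord(b, a, "gap", m, 0)]

    records = [
        # chemical: sensory -> inter -> motor chains plus a reciprocal pair
        SynapseRecord("A01L", "A01R", "chem", 2, 1),
        SynapseRecord("A01R", "A01L", "chem", 1, 0),
        SynapseRecord("A01L", "C01", "chem", 3, 0),
        SynapseRecord("A01R", "C01", "chem", 2, 0),
        SynapseRecord("B01L", "C02L", "chem", 4, 2),
        SynapseRecord("B01R", "C02R", "chem", 3, 1),
        SynapseRecord("C01", "D01", "chem", 2, 0),
        SynapseRecord("C02L", "D01", "chem", 1, 0),
        SynapseRecord("C02R", "D01", "chem", 2, 1),
        SynapseRecord("D01", "E01L", "chem", 3, 0),
        SynapseRecord("D01", "E01R", "chem", 3, 0),
        SynapseRecord("E01L", "E02", "chem", 2, 0),   # GABAergic presynaptic
        SynapseRecord("E01R", "E02", "chem", 1, 0),
        SynapseRecord("E02", "C01", "chem", 1, 0),    # closes a directed cycle
        SynapseRecord("D01", "F01", "chem", 1, 1),
        # gap junctions (paired records)
        *gap("A01L", "A01R", 2),   # overlaps the reciprocal chemical pair
        *gap("B01L", "B01R", 1),
        *gap("B01L", "C01", 1),
        *gap("B01R", "C01", 3),    # triangle B01L-B01R-C01
        *gap("C02L", "D01", 2),
        *gap("C02R", "D01", 1),
        *gap("C02L", "C02R", 1),   # triangle C02L-C02R-D01
        *gap("D01", "E02", 1),
        *gap("E01L", "E01R", 2),
    ]
    return WiringDiagram(neurons=neurons, records=records)
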