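"""Wiring-diagram data model, validation, and adjacency-network construction.

A wiring diagram is a neuron table plus a list of synapse records.  All
analyses consume :class:`AdjacencyNetwork` views built from it under explicit
quantitation conventions (full contact counts, or polyadic contacts counted
at reduced strength).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NeuronRecord",
    "SynapseRecord",
    "WiringDiagram",
    "AdjacencyNetwork",
    "Violation",
    "WiringFormatError",
    "InconsistentDiagramError",
    "load_wiring_diagram",
    "write_wiring_diagram",
    "validate_consistency",
    "build_network",
    "combine_networks",
]

Category = Literal["sensory", "interneuron", "motor"]
SynType = Literal["chem", "gap", "nmj"]

_CATEGORY_CODES = {"S": "sensory", "I": "interneuron", "M": "motor"}
_CATEGORY_TO_CODE = {v: k for k, v in _CATEGORY_CODES.items()}


class WiringFormatError(ValueError):
    """Raised when an input table is malformed (columns, values, references)."""


class InconsistentDiagramError(ValueError):
    """Raised when an operation requires a diagram that passes validation."""


@dataclass(frozen=True)
class NeuronRecord:
    """A named neuron with its category, GABA flag, body side, and class."""

    name: str
    category: Category
    gabaergic: bool = False
    side: str = "none"  # "L", "R", or "none"
    neuron_class: str = ""

    def __post_init__(self):
        if self.category not in ("sensory", "interneuron", "motor"):
            raise WiringFormatError(f"unknown category {self.category!r} for {self.name}")
        if self.side not in ("L", "R", "none"):
            raise WiringFormatError(f"unknown side {self.side!r} for {self.name}")


@dataclass(frozen=True)
class SynapseRecord:
    """One connection record: pre -> post with a contact count.

    ``polyadic`` counts how many of the contacts are polyadic (a presynaptic
    terminal apposed to several candidate postsynaptic processes).
    """

    pre: str
    post: str
    syn_type: SynType
    contacts: int
    polyadic: int = 0

    def __post_init__(self):
        if self.syn_type not in ("chem", "gap", "nmj"):
            raise WiringFormatError(f"unknown synapse type {self.syn_type!r}")
        if self.contacts < 1:
            raise WiringFormatError(
                f"contacts must be >= 1, got {self.contacts} for {self.pre}->{self.post}"
            )
        if not 0 <= self.polyadic <= self.contacts:
            raise WiringFormatError(
                f"polyadic count {self.polyadic} outside [0, {self.contacts}] "
                f"for {self.pre}->{self.post}"
            )
        if self.pre == self.post:
            raise WiringFormatError(f"self-record {self.pre}->{self.post} not allowed")


@dataclass
class WiringDiagram:
    """Neuron table plus synapse records; the single source of truth."""

    neurons: list[NeuronRecord]
    records: list[SynapseRecord]

    def __post_init__(self):
        names = [n.name for n in self.neurons]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise WiringFormatError(f"duplicate neuron names: {dupes}")
        known = set(names)
        unknown = sorted(
            {r.pre for r in self.records if r.pre not in known}
            | {r.post for r in self.records if r.post not in known}
        )
        if unknown:
            raise WiringFormatError(f"synapse records reference undeclared neurons: {unknown}")

    @property
    def neuron_names(self) -> list[str]:
        return [n.name for n in self.neurons]

    def neuron(self, name: str) -> NeuronRecord:
        for n in self.neurons:
            if n.name == name:
                return n
        raise KeyError(name)

    def gabaergic_names(self) -> set[str]:
        return {n.name for n in self.neurons if n.gabaergic}

    def records_of_type(self, syn_type: SynType) -> list[SynapseRecord]:
        return [r for r in self.records if r.syn_type == syn_type]

    def __eq__(self, other) -> bool:
        if not isinstance(other, WiringDiagram):
            return NotImplemented
        return self.neurons == other.neurons and sorted(
            self.records, key=_record_key
        ) == sorted(other.records, key=_record_key)


def _record_key(r: SynapseRecord):
    return (r.syn_type, r.pre, r.post, r.contacts, r.polyadic)


@dataclass
class AdjacencyNetwork:
    """Weighted adjacency-matrix view of one synapse type (or a combination).

    ``weights[i, j]`` is the contact weight from neuron ``names[i]`` to
    ``names[j]``.  Undirected networks carry a symmetric matrix.
    """

    names: list[str]
    weights: np.ndarray
    directed: bool
    quantitation: str = "full"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.names)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights shape {self.weights.shape} != ({n}, {n})")
        if np.any(self.weights < 0):
            raise ValueError("negative weights")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("nonzero diagonal")
        if not self.directed and not np.array_equal(self.weights, self.weights.T):
            raise ValueError("undirected network requires a symmetric matrix")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    def binary(self) -> np.ndarray:
        """0/1 adjacency (connection present irrespective of multiplicity)."""
        return (self.weights > 0).astype(float)

    def binarized(self) -> "AdjacencyNetwork":
        return AdjacencyNetwork(
            names=list(self.names),
            weights=self.binary(),
            directed=self.directed,
            quantitation="binary",
        )

    def subnetwork(self, keep: Sequence[str]) -> "AdjacencyNetwork":
        idx = self.index
        order = [idx[name] for name in keep]
        return AdjacencyNetwork(
            names=list(keep),
            weights=self.weights[np.ix_(order, order)],
            directed=self.directed,
            quantitation=self.quantitation,
        )

    def to_graph(self):
        """Export as a networkx (Di)Graph with ``weight`` edge attributes."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.names)
        rows, cols = np.nonzero(self.weights)
        for i, j in zip(rows, cols):
            if not self.directed and i > j:
                continue
            g.add_edge(self.names[i], self.names[j], weight=float(self.weights[i, j]))
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), str(path))

    def write_edgelist_tsv(self, path: str | Path) -> None:
        rows, cols = np.nonzero(self.weights)
        with open(path, "w") as fh:
            fh.write("pre\tpost\tweight\n")
            for i, j in zip(rows, cols):
                if not self.directed and i > j:
                    continue
                fh.write(f"{self.names[i]}\t{self.names[j]}\t{self.weights[i, j]:g}\n")


@dataclass(frozen=True)
class Violation:
    """A single self-consistency violation (data, not an exception)."""

    kind: str  # "unpaired_gap", "gap_count_mismatch", "duplicate"
    detail: str


# ---------------------------------------------------------------------------
# I/O

NEURON_COLUMNS = ["name", "category", "gabaergic", "side", "class"]
SYNAPSE_COLUMNS = ["pre", "post", "type", "contacts", "polyadic"]


def load_wiring_diagram(neuron_path: str | Path, synapse_path: str | Path) -> WiringDiagram:
    """Load a wiring diagram from the canonical neuron/synapse CSV pair."""
    ntab = pd.read_csv(neuron_path, dtype=str).fillna("")
    missing = [c for c in NEURON_COLUMNS if c not in ntab.columns]
    if missing:
        raise WiringFormatError(f"neuron table missing columns: {missing}")
    stab = pd.read_csv(synapse_path, dtype={"pre": str, "post": str, "type": str})
    missing = [c for c in SYNAPSE_COLUMNS if c not in stab.columns]
    if missing:
        raise WiringFormatError(f"synapse table missing columns: {missing}")

    neurons = []
    for row in ntab.to_dict("records"):
        cat = _CATEGORY_CODES.get(row["category"], row["category"])
        neurons.append(
            NeuronRecord(
                name=row["name"],
                category=cat,
                gabaergic=str(row["gabaergic"]).strip() in ("1", "True", "true"),
                side=row["side"] if row["side"] in ("L", "R") else "none",
                neuron_class=row["class"] or "",
            )
        )

    records = []
    for i, row in enumerate(stab.to_dict("records")):
        contacts = int(row["contacts"])
        if contacts < 0:
            raise WiringFormatError(f"negative contact count in synapse row {i}")
        if row["pre"] == row["post"]:
            raise WiringFormatError(f"synapse row {i}: pre == post == {row['pre']!r}")
        records.append(
            SynapseRecord(
                pre=row["pre"],
                post=row["post"],
                syn_type=row["type"],
                contacts=contacts,
                polyadic=int(row["polyadic"]),
            )
        )
    return WiringDiagram(neurons=neurons, records=records)


def write_wiring_diagram(
    diagram: WiringDiagram, neuron_path: str | Path, synapse_path: str | Path
) -> None:
    """Write the canonical CSV pair; inverse of :func:`load_wiring_diagram`."""
    with open(neuron_path, "w") as fh:
        fh.write(",".join(NEURON_COLUMNS) + "\n")
        for n in diagram.neurons:
            fh.write(
                f"{n.name},{_CATEGORY_TO_CODE[n.category]},{int(n.gabaergic)},"
                f"{n.side if n.side != 'none' else ''},{n.neuron_class}\n"
            )
    with open(synapse_path, "w") as fh:
        fh.write(",".join(SYNAPSE_COLUMNS) + "\n")
        for r in diagram.records:
            fh.write(f"{r.pre},{r.post},{r.syn_type},{r.contacts},{r.polyadic}\n")


# ---------------------------------------------------------------------------
# Validation

def validate_consistency(diagram: WiringDiagram) -> list[Violation]:
    """Check pairing and duplication criteria; an empty report means consistent.

    Gap-junction records must come in (i, j)/(j, i) pairs.  Duplicate records
    for the same ordered pair and type are flagged for every type.
    """
    violations: list[Violation] = []

    seen: dict[tuple, int] = {}
    for r in diagram.records:
        key = (r.syn_type, r.pre, r.post)
        seen[key] = seen.get(key, 0) + 1
    for (syn_type, pre, post), count in sorted(seen.items()):
        if count > 1:
            violations.append(
                Violation("duplicate", f"{count} {syn_type} records for {pre}->{post}")
            )

    gap = {(r.pre, r.post): r.contacts for r in diagram.records_of_type("gap")}
    for (a, b), contacts in sorted(gap.items()):
        if (b, a) not in gap:
            violations.append(Violation("unpaired_gap", f"gap record {a}->{b} has no {b}->{a}"))
        elif a < b and gap[(b, a)] != contacts:
            violations.append(
                Violation(
                    "gap_count_mismatch",
                    f"gap records {a}<->{b} disagree: {contacts} vs {gap[(b, a)]}",
                )
            )
    return violations


# ---------------------------------------------------------------------------
# Network construction

def _effective_weight(record: SynapseRecord, quantitation: str, polyad_weight: float) -> float:
    if quantitation == "full":
        return float(record.contacts)
    if quantitation == "polyad_split":
        return (record.contacts - record.polyadic) + polyad_weight * record.polyadic
    raise ValueError(f"unknown quantitation {quantitation!r}")


def build_network(
    diagram: WiringDiagram,
    syn_type: Literal["chem", "gap"],
    quantitation: str = "full",
    polyad_weight: float = 0.5,
    keep_isolated: bool = False,
    check: bool = True,
) -> AdjacencyNetwork:
    """Build the adjacency network of one synapse type.

    Chemical records give a directed matrix of contact counts; gap records
    give a symmetric matrix with paired (i, j)/(j, i) records merged (max of
    the two stated counts), not double-counted.  Under ``polyad_split``
    quantitation each polyadic contact contributes ``polyad_weight`` instead
    of 1.  Neurons without any synapse of the type are dropped unless
    ``keep_isolated``.
    """
    if syn_type not in ("chem", "gap"):
        raise ValueError(f"syn_type must be 'chem' or 'gap', got {syn_type!r}")
    if check:
        bad = []
        for v in validate_consistency(diagram):
            if v.kind == "unpaired_gap":
                # count mismatches are tolerated (merged by max); missing
                # partner records are not
                if syn_type == "gap":
                    bad.append(v)
            elif v.kind == "duplicate" and f" {syn_type} records" in v.detail:
                bad.append(v)
        if bad:
            raise InconsistentDiagramError(
                f"diagram fails validate_consistency for type {syn_type!r}: "
                f"{[v.detail for v in bad[:5]]}"
            )

    names = diagram.neuron_names
    idx = {name: i for i, name in enumerate(names)}
    n = len(names)
    A = np.zeros((n, n))

    if syn_type == "chem":
        for r in diagram.records_of_type("chem"):
            A[idx[r.pre], idx[r.post]] += _effective_weight(r, quantitation, polyad_weight)
        directed = True
    else:
        merged: dict[tuple[int, int], float] = {}
        for r in diagram.records_of_type("gap"):
            i, j = idx[r.pre], idx[r.post]
            key = (min(i, j), max(i, j))
            w = _effective_weight(r, quantitation, polyad_weight)
            merged[key] = max(merged.get(key, 0.0), w)  # paired records merged by max
        for (i, j), w in merged.items():
            A[i, j] = A[j, i] = w
        directed = False

    if not keep_isolated:
        used = np.flatnonzero((A.sum(axis=0) + A.sum(axis=1)) > 0)
        names = [names[i] for i in used]
        A = A[np.ix_(used, used)]
    return AdjacencyNetwork(names=names, weights=A, directed=directed, quantitation=quantitation)


def combine_networks(
    gap: AdjacencyNetwork,
    chem: AdjacencyNetwork,
    mode: Literal["binary", "weighted"] = "binary",
) -> AdjacencyNetwork:
    """Union of the gap and chemical networks as one directed network.

    Gap junctions are treated as double-sided directed connections.  In
    ``binary`` mode a connection is present if either network has one; in
    ``weighted`` mode multiplicities add, ``A[i, j] = m_chem(i->j) + m_gap(i, j)``.
    """
    if gap.names != chem.names:
        raise ValueError("gap and chem networks must share the same neuron index")
    gap_sym = gap.weights if not gap.directed else np.maximum(gap.weights, gap.weights.T)
    if mode == "binary":
        A = ((chem.weights > 0) | (gap_sym > 0)).astype(float)
    elif mode == "weighted":
        A = chem.weights + gap_sym
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AdjacencyNetwork(
        names=list(gap.names), weights=A, directed=True, quantitation=f"combined_{mode}"
    )


def align_networks(
    gap: AdjacencyNetwork, chem: AdjacencyNetwork, diagram: WiringDiagram | None = None
) -> tuple[AdjacencyNetwork, AdjacencyNetwork]:
    """Re-embed both networks on a common neuron index (their name union).

    Needed because :func:`build_network` drops isolated neurons per type;
    combining or comparing the two requires one shared index.  Order follows
    the diagram when given, otherwise sorted union.
    """
    if diagram is not None:
        union = [nm for nm in diagram.neuron_names if nm in set(gap.names) | set(chem.names)]
    else:
        union = sorted(set(gap.names) | set(chem.names))
    return _embed(gap, union), _embed(chem, union)


def _embed(net: AdjacencyNetwork, names: list[str]) -> AdjacencyNetwork:
    idx = {name: i for i, name in enumerate(names)}
    A = np.zeros((len(names), len(names)))
    old = np.array([idx[nm] for nm in net.names])
    A[np.ix_(old, old)] = net.weights
    return AdjacencyNetwork(
        names=list(names), weights=A, directed=net.directed, quantitation=net.quantitation
    )
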