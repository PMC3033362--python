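"""Error-sensitivity analysis: random relocation of synaptic contacts and
ensemble recomputation of global network statistics.

Each individual contact (each unit of multiplicity) is independently
relocated with its type's probability to a uniformly random ordered pair
(chemical) or unordered pair (gap junction), excluding self-pairs; the total
contact count per type is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import smallworld
from .components import connected_components
from .spectral import dynamics_matrix, eigenmodes
from .wiring import (
    AdjacencyNetwork,
    SynapseRecord,
    WiringDiagram,
    align_networks,
    build_network,
    combine_networks,
)

__all__ = ["EditSpec", "edit_diagram", "robustness_ensemble", "spectrum_displacements"]

METRICS = (
    "giant_component_size",
    "characteristic_path_length",
    "clustering",
    "small_world_ness",
    "max_in_degree",
    "max_out_degree",
    "spectrum",
)


@dataclass
class EditSpec:
    p_gap: float = 0.05
    p_chem: float = 0.05
    n_networks: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_gap <= 1 and 0 <= self.p_chem <= 1):
            raise ValueError("relocation probabilities must lie in [0,1]")
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")


def _relocate(
    contacts: list[tuple[str, str]],
    p: float,
    names: list[str],
    ordered: bool,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    out = []
    n = len(names)
    for pair in contacts:
        if rng.random() < p:
            i = rng.integers(0, n)
            j = rng.integers(0, n - 1)
            if j >= i:
                j += 1
            a, b = names[i], names[j]
            out.append((a, b) if ordered else tuple(sorted((a, b))))
        else:
            out.append(pair if ordered else tuple(sorted(pair)))
    return out


def edit_diagram(diagram: WiringDiagram, spec: EditSpec, draw_index: int = 0) -> WiringDiagram:
    """One randomly edited copy of the diagram (deterministic per seed, draw).

    Contacts are expanded to multiplicity units, relocated independently,
    and re-aggregated into records.  Polyadic flags follow their contacts
    proportionally (rounded down); nmj records pass through untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, draw_index]))
    names = diagram.neuron_names

    chem_units: list[tuple[str, str]] = []
    poly_units: list[bool] = []
    for r in diagram.records_of_type("chem"):
        chem_units.extend([(r.pre, r.post)] * r.contacts)
        poly_units.extend([True] * r.polyadic + [False] * (r.contacts - r.polyadic))
    gap_units: list[tuple[str, str]] = []
    seen = set()
    for r in diagram.records_of_type("gap"):
        key = tuple(sorted((r.pre, r.post)))
        if key in seen:
            continue  # paired record: count each junction once
        seen.add(key)
        gap_units.extend([key] * r.contacts)

    new_chem = _relocate(chem_units, spec.p_chem, names, ordered=True, rng=rng)
    new_gap = _relocate(gap_units, spec.p_gap, names, ordered=False, rng=rng)

    records: list[SynapseRecord] = []
    agg: dict[tuple[str, str], list[int]] = {}
    for pair, poly in zip(new_chem, poly_units):
        tot = agg.setdefault(pair, [0, 0])
        tot[0] += 1
        tot[1] += int(poly)
    for (pre, post), (m, q) in sorted(agg.items()):
        records.append(SynapseRecord(pre, post, "chem", m, q))
    gagg: dict[tuple[str, str], int] = {}
    for pair in new_gap:
        gagg[pair] = gagg.get(pair, 0) + 1
    for (a, b), m in sorted(gagg.items()):
        records.append(SynapseRecord(a, b, "gap", m, 0))
        records.append(SynapseRecord(b, a, "gap", m, 0))
    records.extend(diagram.records_of_type("nmj"))
    return WiringDiagram(neurons=list(diagram.neurons), records=records)


def _diagram_metrics(diagram: WiringDiagram, metrics: list[str], seed: int) -> dict:
    gap = build_network(diagram, "gap", check=False)
    chem = build_network(diagram, "chem", check=False)
    gap_a, chem_a = align_networks(gap, chem, diagram)
    combined = combine_networks(gap_a, chem_a, mode="binary")
    out: dict[str, object] = {}
    part = connected_components(combined, "strong")
    if "giant_component_size" in metrics:
        out["giant_component_size"] = len(part.giant)
    giant = combined.subnetwork([nm for nm in combined.names if nm in part.giant])
    if "characteristic_path_length" in metrics:
        out["characteristic_path_length"] = smallworld.path_stats(giant).characteristic_length
    if "clustering" in metrics:
        out["clustering"] = smallworld.clustering(giant, "out")[1]
    if "small_world_ness" in metrics:
        from .null_models import NullEnsembleSpec

        report = smallworld.small_world_ness(
            combined,
            NullEnsembleSpec(
                kind="directed_degree_reciprocity_preserving",
                n_samples=10,
                swaps_per_edge=10,
                seed=seed,
            ),
        )
        out["small_world_ness"] = report.S
    if "max_in_degree" in metrics:
        out["max_in_degree"] = int(combined.binary().sum(axis=0).max())
    if "max_out_degree" in metrics:
        out["max_out_degree"] = int(combined.binary().sum(axis=1).max())
    if "spectrum" in metrics:
        wg, wc = align_networks(
            build_network(diagram, "gap", check=False),
            build_network(diagram, "chem", check=False),
            diagram,
        )
        signs = {nm: (-1 if nm in diagram.gabaergic_names() else 1) for nm in wg.names}
        keep = [nm for nm in wg.names if nm in part.giant]
        _, M = dynamics_matrix(wg.subnetwork(keep), wc.subnetwork(keep), signs)
        out["spectrum"] = eigenmodes(M).eigenvalues
    return out


def robustness_ensemble(
    diagram: WiringDiagram, spec: EditSpec, metrics: list[str] | None = None
) -> dict:
    """Metric distributions over the edited-diagram ensemble.

    Returns per-metric values across the ensemble with mean, sd, and the
    unedited value; the ``spectrum`` metric reports, for every unedited
    eigenvalue, the displacement to the nearest edited eigenvalue.
    """
    metrics = list(metrics or ("giant_component_size", "characteristic_path_length"))
    unknown = [m for m in metrics if m not in METRICS]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}; available: {METRICS}")
    base = _diagram_metrics(diagram, metrics, spec.seed)
    rows = [
        _diagram_metrics(edit_diagram(diagram, spec, k), metrics, spec.seed)
        for k in range(spec.n_networks)
    ]
    result: dict[str, dict] = {}
    for m in metrics:
        if m == "spectrum":
            disp = np.array(
                [spectrum_displacements(base["spectrum"], row["spectrum"]) for row in rows]
            )
            result[m] = {
                "unedited_eigenvalues": base["spectrum"],
                "edited_spectra": [row["spectrum"] for row in rows],
                "nearest_displacement_mean": disp.mean(axis=0),
                "nearest_displacement_max": disp.max(axis=0),
            }
        else:
            vals = np.array([row[m] for row in rows], dtype=float)
            result[m] = {
                "unedited": float(base[m]),
                "values": vals,
                "mean": float(vals.mean()),
                "sd": float(vals.std()),
            }
    return result


def spectrum_displacements(reference: np.ndarray, edited: np.ndarray) -> np.ndarray:
    """For each reference eigenvalue, the distance to the nearest edited one."""
    ref = np.asarray(reference).reshape(-1, 1)
    ed = np.asarray(edited).reshape(1, -1)
    return np.abs(ref - ed).min(axis=1)
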