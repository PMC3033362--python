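import numpy as np
import pytest

from nervenet.synthetic import SynthParams, generate_connectome
from nervenet.wiring import (
    AdjacencyNetwork,
    InconsistentDiagramError,
    NeuronRecord,
    SynapseRecord,
    WiringDiagram,
    WiringFormatError,
    align_networks,
    build_network,
    combine_networks,
    load_wiring_diagram,
    validate_consistency,
    write_wiring_diagram,
)


def _neurons(*names):
    return [NeuronRecord(n, "interneuron") for n in names]


class TestLoad:
    def test_minimal_diagram(self, tmp_path):
        (tmp_path / "n.csv").write_text(
            "name,category,gabaergic,side,class\nA,S,0,,A\nB,I,1,L,B\nC,M,0,,C\n"
        )
        (tmp_path / "s.csv").write_text(
            "pre,post,type,contacts,polyadic\nA,B,chem,3,1\nB,C,gap,2,0\n"
        )
        d = load_wiring_diagram(tmp_path / "n.csv", tmp_path / "s.csv")
        assert len(d.neurons) == 3
        assert len(d.records) == 2
        assert d.neuron("B").gabaergic and d.neuron("B").side == "L"
        assert d.neuron("A").category == "sensory"

    def test_undeclared_neuron_listed(self, tmp_path):
        (tmp_path / "n.csv").write_text("name,category,gabaergic,side,class\nA,S,0,,A\n")
        (tmp_path / "s.csv").write_text("pre,post,type,contacts,polyadic\nA,XXX,chem,1,0\n")
        with pytest.raises(WiringFormatError, match="XXX"):
            load_wiring_diagram(tmp_path / "n.csv", tmp_path / "s.csv")

    def test_missing_column(self, tmp_path):
        (tmp_path / "n.csv").write_text("name,category\nA,S\n")
        (tmp_path / "s.csv").write_text("pre,post,type,contacts,polyadic\n")
        with pytest.raises(WiringFormatError, match="missing columns"):
            load_wiring_diagram(tmp_path / "n.csv", tmp_path / "s.csv")

    def test_self_record_rejected(self, tmp_path):
        (tmp_path / "n.csv").write_text("name,category,gabaergic,side,class\nA,S,0,,A\n")
        (tmp_path / "s.csv").write_text("pre,post,type,contacts,polyadic\nA,A,chem,1,0\n")
        with pytest.raises(WiringFormatError, match="pre == post"):
            load_wiring_diagram(tmp_path / "n.csv", tmp_path / "s.csv")

    def test_round_trip_identity(self, tmp_path):
        d = generate_connectome(SynthParams(n_neurons=60, seed=3))
        write_wiring_diagram(d, tmp_path / "n.csv", tmp_path / "s.csv")
        d2 = load_wiring_diagram(tmp_path / "n.csv", tmp_path / "s.csv")
        assert d2 == d

    def test_round_trip_bytes_deterministic(self, tmp_path):
        for k in (1, 2):
            d = generate_connectome(SynthParams(n_neurons=40, seed=9))
            write_wiring_diagram(d, tmp_path / f"n{k}.csv", tmp_path / f"s{k}.csv")
        assert (tmp_path / "n1.csv").read_bytes() == (tmp_path / "n2.csv").read_bytes()
        assert (tmp_path / "s1.csv").read_bytes() == (tmp_path / "s2.csv").read_bytes()


class TestValidate:
    def test_paired_gap_consistent(self):
        d = WiringDiagram(
            _neurons("A", "B"),
            [SynapseRecord("A", "B", "gap", 2), SynapseRecord("B", "A", "gap", 2)],
        )
        assert validate_consistency(d) == []

    def test_unpaired_gap_flagged(self):
        d = WiringDiagram(_neurons("A", "B"), [SynapseRecord("A", "B", "gap", 2)])
        report = validate_consistency(d)
        assert [v.kind for v in report] == ["unpaired_gap"]

    def test_duplicate_chemical_flagged(self):
        d = WiringDiagram(
            _neurons("A", "B"),
            [SynapseRecord("A", "B", "chem", 1), SynapseRecord("A", "B", "chem", 2)],
        )
        report = validate_consistency(d)
        assert [v.kind for v in report] == ["duplicate"]

    def test_gap_count_mismatch_flagged(self):
        d = WiringDiagram(
            _neurons("A", "B"),
            [SynapseRecord("A", "B", "gap", 2), SynapseRecord("B", "A", "gap", 5)],
        )
        kinds = {v.kind for v in validate_consistency(d)}
        assert kinds == {"gap_count_mismatch"}


class TestBuild:
    def test_single_directed_edge(self):
        d = WiringDiagram(_neurons("A", "B"), [SynapseRecord("A", "B", "chem", 3)])
        net = build_network(d, "chem")
        i, j = net.index["A"], net.index["B"]
        assert net.weights[i, j] == 3 and net.weights[j, i] == 0
        assert net.directed

    def test_paired_gap_not_double_counted(self):
        d = WiringDiagram(
            _neurons("A", "B"),
            [SynapseRecord("A", "B", "gap", 2), SynapseRecord("B", "A", "gap", 2)],
        )
        net = build_network(d, "gap")
        assert net.weights[0, 1] == 2 == net.weights[1, 0]

    def test_polyad_split_weight(self):
        d = WiringDiagram(_neurons("A", "B"), [SynapseRecord("A", "B", "chem", 2, 2)])
        net = build_network(d, "chem", quantitation="polyad_split")
        assert net.weights[net.index["A"], net.index["B"]] == 1.0

    def test_gap_symmetric_exactly(self, small_synthetic):
        net = build_network(small_synthetic, "gap")
        assert np.max(np.abs(net.weights - net.weights.T)) == 0

    def test_chem_total_contacts_conserved(self, small_synthetic):
        net = build_network(small_synthetic, "chem")
        total = sum(r.contacts for r in small_synthetic.records_of_type("chem"))
        assert net.weights.sum() == total

    def test_refuses_unpaired_gap(self):
        d = WiringDiagram(_neurons("A", "B"), [SynapseRecord("A", "B", "gap", 2)])
        with pytest.raises(InconsistentDiagramError, match="validate_consistency"):
            build_network(d, "gap")

    def test_isolated_dropped_by_default(self):
        d = WiringDiagram(_neurons("A", "B", "C"), [SynapseRecord("A", "B", "chem", 1)])
        assert build_network(d, "chem").names == ["A", "B"]
        assert build_network(d, "chem", keep_isolated=True).n == 3

    def test_nmj_excluded(self):
        d = WiringDiagram(
            _neurons("A", "B"),
            [SynapseRecord("A", "B", "chem", 1), SynapseRecord("A", "B", "nmj", 4)],
        )
        net = build_network(d, "chem")
        assert net.weights.sum() == 1


class TestCombine:
    def test_gap_only_binary(self):
        d = WiringDiagram(
            _neurons("A", "B"),
            [SynapseRecord("A", "B", "gap", 3), SynapseRecord("B", "A", "gap", 3)],
        )
        gap = build_network(d, "gap")
        chem = AdjacencyNetwork(gap.names, np.zeros((2, 2)), directed=True)
        comb = combine_networks(gap, chem, "binary")
        assert comb.weights[0, 1] == 1 == comb.weights[1, 0]

    def test_weighted_sum(self):
        d = WiringDiagram(
            _neurons("A", "B"),
            [
                SynapseRecord("A", "B", "chem", 3),
                SynapseRecord("A", "B", "gap", 2),
                SynapseRecord("B", "A", "gap", 2),
            ],
        )
        gap = build_network(d, "gap", keep_isolated=True)
        chem = build_network(d, "chem", keep_isolated=True)
        comb = combine_networks(gap, chem, "weighted")
        i, j = comb.index["A"], comb.index["B"]
        assert comb.weights[i, j] == 5 and comb.weights[j, i] == 2

    def test_empty_gap_identity(self, fixture_networks):
        gap, chem = fixture_networks
        empty = AdjacencyNetwork(chem.names, np.zeros_like(chem.weights), directed=False)
        comb = combine_networks(empty, chem, "weighted")
        assert np.array_equal(comb.weights, chem.weights)

    def test_weighted_equals_chem_plus_symmetrized_gap(self, fixture_networks):
        gap, chem = fixture_networks
        comb = combine_networks(gap, chem, "weighted")
        assert np.array_equal(comb.weights, chem.weights + gap.weights)

    def test_index_mismatch_rejected(self, fixture_networks):
        gap, chem = fixture_networks
        with pytest.raises(ValueError, match="index"):
            combine_networks(gap.subnetwork(gap.names[:-1]), chem)


class TestAdjacencyNetwork:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            AdjacencyNetwork(["a", "b"], np.array([[0, 1], [0, 0]]), directed=False)
        with pytest.raises(ValueError, match="diagonal"):
            AdjacencyNetwork(["a"], np.array([[1.0]]), directed=True)
        with pytest.raises(ValueError, match="negative"):
            AdjacencyNetwork(["a", "b"], np.array([[0, -1], [0, 0]]), directed=True)

    def test_graphml_and_tsv_export(self, tmp_path, fixture_networks):
        import networkx as nx

        gap, chem = fixture_networks
        chem.write_graphml(tmp_path / "chem.graphml")
        g = nx.read_graphml(tmp_path / "chem.graphml")
        assert g.number_of_edges() == int((chem.weights > 0).sum())
        gap.write_edgelist_tsv(tmp_path / "gap.tsv")
        lines = (tmp_path / "gap.tsv").read_text().strip().splitlines()
        assert lines[0] == "pre\tpost\tweight"
        assert len(lines) - 1 == int((np.triu(gap.weights) > 0).sum())
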