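import numpy as np
import pytest

from nervenet.spectral import (
    DynamicsParams,
    affinity_layout,
    circuit_probability_bound,
    dynamics_matrix,
    eigenmodes,
    graph_laplacian,
    pseudospectrum,
    signal_flow_layout,
    simulate_response,
)
from nervenet.wiring import AdjacencyNetwork
from tests.conftest import make_net


class TestLaplacian:
    def test_single_edge(self):
        net = make_net([(0, 1)])
        assert np.linalg.eigvalsh(graph_laplacian(net)) == pytest.approx([0, 2], abs=1e-10)

    def test_path3(self, path3):
        assert np.linalg.eigvalsh(graph_laplacian(path3)) == pytest.approx([0, 1, 3], abs=1e-10)

    def test_complete_graph(self):
        n = 6
        net = make_net([(i, j) for i in range(n) for j in range(i + 1, n)])
        vals = np.linalg.eigvalsh(graph_laplacian(net))
        assert vals == pytest.approx([0] + [n] * (n - 1), abs=1e-10)

    def test_asymmetric_rejected(self):
        net = make_net([(0, 1)], directed=True)
        with pytest.raises(ValueError):
            graph_laplacian(net)

    def test_psd_and_connectivity(self, fixture_networks):
        gap, _ = fixture_networks
        from nervenet.components import giant_component

        g = giant_component(gap)
        vals = np.linalg.eigvalsh(graph_laplacian(g))
        assert vals[0] == pytest.approx(0, abs=1e-10)
        assert vals[1] > 0  # algebraic connectivity > 0 iff connected


class TestDynamicsMatrix:
    def test_gap_only_is_minus_laplacian(self, path3):
        _, M = dynamics_matrix(path3)
        assert np.allclose(M, -graph_laplacian(path3))

    def test_gaba_sign_applied(self):
        chem = make_net([(0, 1)], directed=True, names=["A", "B"], weights=[2.0])
        gap = AdjacencyNetwork(["A", "B"], np.zeros((2, 2)), directed=False)
        _, M = dynamics_matrix(gap, chem, signs={"A": -1})
        assert M[1, 0] == -2  # post row, pre column

    def test_missing_sign_raises(self):
        chem = make_net([(0, 1)], directed=True, names=["A", "B"])
        gap = AdjacencyNetwork(["A", "B"], np.zeros((2, 2)), directed=False)
        with pytest.raises(ValueError, match="sign"):
            dynamics_matrix(gap, chem, signs={})

    def test_leak_shifts_spectrum_exactly(self, path3):
        params = DynamicsParams(membrane_conductance_pS=10, gap_conductance_pS=100,
                                include_leak=True)
        _, M0 = dynamics_matrix(path3)
        _, M1 = dynamics_matrix(path3, params=params)
        v0 = np.sort(np.linalg.eigvalsh(M0))
        v1 = np.sort(np.linalg.eigvalsh(M1))
        assert v1 == pytest.approx(v0 - 0.1, abs=1e-12)

    def test_gap_only_negative_semidefinite(self, fixture_networks):
        gap, _ = fixture_networks
        _, M = dynamics_matrix(gap)
        vals = np.linalg.eigvalsh(M)
        assert vals.max() <= 1e-10
        assert np.allclose(np.sort(vals), np.sort(-np.linalg.eigvalsh(graph_laplacian(gap))))


class TestEigenmodes:
    def test_single_edge_decay_times(self):
        net = make_net([(0, 1)])
        _, M = dynamics_matrix(net)
        ea = eigenmodes(M)
        times = sorted(ea.decay_times_tau)
        assert times[0] == pytest.approx(0.5)
        assert np.isinf(times[1])

    def test_sparseness_extremes(self):
        M = np.diag([0.0, -1.0, -2.0, -3.0])
        ea = eigenmodes(M)
        assert ea.sparseness == pytest.approx([1, 1, 1, 1])
        # flat mode on n=4 has L1 norm 2
        flat = np.ones(4) / 2
        assert np.abs(flat).sum() == pytest.approx(2.0)

    def test_residuals_small_random_symmetric(self, rng):
        A = rng.normal(size=(20, 20))
        M = (A + A.T) / 2
        ea = eigenmodes(M)
        assert ea.residuals.max() < 1e-8

    def test_conjugate_pairs_for_real_matrix(self, rng):
        M = rng.normal(size=(12, 12))
        ea = eigenmodes(M)
        vals = ea.eigenvalues
        complex_vals = vals[np.abs(vals.imag) > 1e-12]
        assert len(complex_vals) % 2 == 0
        conj = np.sort_complex(np.conj(complex_vals))
        assert np.allclose(np.sort_complex(complex_vals), conj)

    def test_sign_convention_deterministic(self, rng):
        A = rng.normal(size=(10, 10))
        M = (A + A.T) / 2
        v1 = eigenmodes(M).eigenmodes
        v2 = eigenmodes(M.copy()).eigenmodes
        assert np.array_equal(v1, v2)
        top = np.argmax(np.abs(v1), axis=0)
        assert (v1[top, np.arange(10)].real > 0).all()


class TestSimulateResponse:
    def test_eigenmode_evolution(self, path3):
        _, M = dynamics_matrix(path3)
        ea = eigenmodes(M)
        k = 1
        u = ea.eigenmodes[:, k].real
        lam = ea.eigenvalues[k].real
        times = np.array([0.0, 0.5, 1.0, 2.0])
        traj = simulate_response(M, u, times)
        for t, row in zip(times, traj):
            assert row == pytest.approx(np.exp(lam * t) * u, abs=1e-10)

    def test_charge_conservation(self, fixture_networks):
        gap, _ = fixture_networks
        from nervenet.components import giant_component

        g = giant_component(gap)
        _, M = dynamics_matrix(g)
        v0 = np.zeros(g.n)
        v0[0] = 1.0
        traj = simulate_response(M, v0, np.linspace(0, 20, 10))
        assert np.abs(traj.sum(axis=1) - 1.0).max() < 1e-10

    def test_long_time_limit_is_mean(self, path3):
        _, M = dynamics_matrix(path3)
        v0 = np.array([1.0, 0.0, 0.0])
        traj = simulate_response(M, v0, np.array([0.0, 500.0]))
        assert traj[-1] == pytest.approx(np.full(3, 1 / 3), abs=1e-8)

    def test_tau_rescaling_identity(self, path3):
        _, M = dynamics_matrix(path3)
        t = np.array([0.0, 1.0, 2.0])
        a = simulate_response(M, np.array([1.0, 0, 0]), t)
        b = simulate_response(M / 2, np.array([1.0, 0, 0]), 2 * t)
        assert np.allclose(a, b)

    def test_expm_path_agrees_with_eigen_path(self, rng):
        M = rng.normal(size=(8, 8))
        v0 = rng.normal(size=8)
        times = np.array([0.0, 0.3, 1.0])
        from scipy.linalg import expm

        traj = simulate_response(M, v0, times)
        for t, row in zip(times, traj):
            assert np.allclose(row, expm(M * t) @ v0, rtol=1e-6, atol=1e-8)


class TestSignalFlowLayout:
    def test_chain_exact(self):
        net = make_net([(0, 1), (1, 2)], directed=True, names=["a", "b", "c"])
        z = signal_flow_layout(net)
        assert z["a"] == pytest.approx(-1, abs=1e-8)
        assert z["b"] == pytest.approx(0, abs=1e-8)
        assert z["c"] == pytest.approx(1, abs=1e-8)

    def test_cycle_frustrated_flat(self):
        net = make_net([(0, 1), (1, 2), (2, 0)], directed=True)
        z = np.array(list(signal_flow_layout(net).values()))
        assert np.allclose(z, 0, atol=1e-8)

    def test_single_neuron(self):
        net = make_net([], n=1, directed=True)
        assert signal_flow_layout(net) == {"v0": 0.0}

    def test_gradient_at_optimum(self):
        # stationarity: L_sym z = d_in - d_out
        rng = np.random.default_rng(2)
        B = (rng.random((15, 15)) < 0.2).astype(float)
        np.fill_diagonal(B, 0)
        net = AdjacencyNetwork([f"v{i}" for i in range(15)], B, directed=True)
        z = np.array([signal_flow_layout(net)[f"v{i}"] for i in range(15)])
        W = B + B.T
        L = np.diag(W.sum(1)) - W
        b = B.sum(0) - B.sum(1)
        assert np.linalg.norm(L @ z - b) < 1e-8

    def test_dag_topological_depth(self):
        # two parallel chains from one source to one sink, equal lengths
        net = make_net([(0, 1), (1, 3), (0, 2), (2, 3)], directed=True)
        z = signal_flow_layout(net)
        # depths 0,1,1,2 under the zero-mean gauge: objective minimum is 0
        assert z["v0"] == pytest.approx(-1.0, abs=1e-8)
        assert z["v1"] == pytest.approx(0.0, abs=1e-8)
        assert z["v3"] == pytest.approx(1.0, abs=1e-8)


class TestAffinityLayout:
    def test_two_cliques_separated_by_fiedler_sign(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
        edges += [(4, 5)]
        net = make_net(edges)
        xy = affinity_layout(net)
        xs = {nm: v[0] for nm, v in xy.items()}
        left = {xs[f"v{i}"] > 0 for i in range(4)}
        right = {xs[f"v{i}"] > 0 for i in range(6, 10)}
        assert left == {True} or left == {False}
        assert right != left

    def test_path_monotone_fiedler(self):
        net = make_net([(i, i + 1) for i in range(7)])
        xy = affinity_layout(net)
        xs = [xy[f"v{i}"][0] for i in range(8)]
        d = np.diff(xs)
        assert (d > 0).all() or (d < 0).all()

    def test_too_small_component_raises(self):
        net = make_net([(0, 1)])
        with pytest.raises(ValueError):
            affinity_layout(net)


class TestCircuitBound:
    def test_hand_value(self):
        assert circuit_probability_bound(10, [3], 2) == pytest.approx(3 / 45)

    def test_k_too_large_gives_zero(self):
        assert circuit_probability_bound(10, [3, 4], 5) == 0.0

    def test_capped_at_one(self):
        assert circuit_probability_bound(10, [9], 2, n_circuits=10**9) == 1.0

    def test_k_exceeds_n_raises(self):
        with pytest.raises(ValueError):
            circuit_probability_bound(5, [3], 6)


class TestPseudospectrum:
    def test_normal_matrix_distance(self):
        M = np.diag([0.0, -1.0])
        res, ims, f = pseudospectrum(M, (-0.35, -0.25), (-0.01, 0.01), resolution=3)
        assert f[1, 1] == pytest.approx(abs(-0.3 - 0.0), abs=0.02)

    def test_normal_matrix_disks(self, rng):
        # for a normal matrix, sigma_min(zI - M) = distance to the spectrum
        A = rng.normal(size=(6, 6))
        M = (A + A.T) / 2
        vals = np.linalg.eigvalsh(M)
        res, ims, f = pseudospectrum(M, (vals.min(), vals.max()), (-0.5, 0.5), resolution=12)
        for a, im in enumerate(ims):
            for b, re in enumerate(res):
                dist = np.abs(complex(re, im) - vals).min()
                assert f[a, b] == pytest.approx(dist, abs=1e-10)

    def test_nonnormal_amplification(self):
        M = np.array([[0.0, 10.0], [0.0, 0.0]])
        res, ims, f = pseudospectrum(M, (0.9, 1.1), (-0.01, 0.01), resolution=3)
        # z = 1 is far outside the 0.1-disk around 0, yet sigma_min < 0.1
        assert f[1, 1] < 0.1
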