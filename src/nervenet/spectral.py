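"""Linear-dynamics matrices, eigenmode analysis, spectral layouts, response
simulation, circuit-probability bounds, and pseudospectra.

The membrane-potential dynamics are dv/dt = (1/tau) M v, with tau = C_m/g.
For a gap-junction network alone M = -L (negative weighted graph Laplacian);
chemical connections add signed off-diagonal terms (negative columns for
GABAergic presynaptic neurons); an optional leak term shifts the whole
spectrum by -g_m/g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .components import giant_component
from .wiring import AdjacencyNetwork

__all__ = [
    "DynamicsParams",
    "EigenAnalysis",
    "graph_laplacian",
    "dynamics_matrix",
    "eigenmodes",
    "simulate_response",
    "signal_flow_layout",
    "affinity_layout",
    "circuit_probability_bound",
    "pseudospectrum",
]


@dataclass
class DynamicsParams:
    """Electrical constants; decay times are reported in units of tau unless
    physical constants are supplied."""

    capacitance_pF: float = 1.0
    gap_conductance_pS: float = 100.0
    chem_conductance_pS: float = 100.0   # assumed equal to the gap conductance
    membrane_conductance_pS: float = 10.0
    include_leak: bool = False

    def __post_init__(self):
        if min(
            self.capacitance_pF,
            self.gap_conductance_pS,
            self.chem_conductance_pS,
            self.membrane_conductance_pS,
        ) <= 0:
            raise ValueError("all electrical constants must be positive")

    @property
    def tau_ms(self) -> float:
        # pF / pS = 1e-12 F / 1e-12 S = seconds; report in ms
        return 1000.0 * self.capacitance_pF / self.gap_conductance_pS

    @property
    def leak_ratio(self) -> float:
        return self.membrane_conductance_pS / self.gap_conductance_pS


@dataclass
class EigenAnalysis:
    names: list[str]
    eigenvalues: np.ndarray      # complex, sorted by descending real part
    eigenmodes: np.ndarray       # columns, unit L2 norm
    decay_times_tau: np.ndarray  # per-mode 1/|Re lambda| in units of tau
    sparseness: np.ndarray       # per-mode L1 norm of the unit-L2 mode
    residuals: np.ndarray        # ||M v - lambda v|| per mode

    def mode(self, k: int) -> dict[str, complex]:
        return dict(zip(self.names, self.eigenmodes[:, k]))


def graph_laplacian(net: AdjacencyNetwork) -> np.ndarray:
    """L = D - A for a symmetric weighted network (positive semidefinite)."""
    A = net.weights
    if not np.allclose(A, A.T):
        raise ValueError("graph_laplacian requires a symmetric (undirected) network")
    return np.diag(A.sum(axis=1)) - A


def dynamics_matrix(
    gap: AdjacencyNetwork | None,
    chem: AdjacencyNetwork | None = None,
    signs: dict[str, int] | None = None,
    params: DynamicsParams | None = None,
) -> tuple[list[str], np.ndarray]:
    """Build the combined linear-dynamics matrix in units of 1/tau.

    M[i, j] = m_gap(i, j) + s_j * m_chem(j -> i) for i != j, and
    M[i, i] = -sum_j m_gap(i, j) - leak.  ``signs`` maps neuron names to +/-1
    (GABAergic neurons are -1); a sign is required for every neuron with an
    outgoing chemical connection.  With no chemical network this reduces to
    -L(gap) (minus an optional leak shift).
    """
    params = params or DynamicsParams()
    if gap is None and chem is None:
        raise ValueError("at least one of gap/chem must be provided")
    if gap is not None and chem is not None and gap.names != chem.names:
        raise ValueError("gap and chem networks must share the same neuron index")
    names = list((gap or chem).names)
    n = len(names)
    M = np.zeros((n, n))

    if gap is not None:
        G = gap.weights if not gap.directed else np.maximum(gap.weights, gap.weights.T)
        M += G - np.diag(G.sum(axis=1))  # equals -Laplacian

    if chem is not None and chem.weights.any():
        signs = signs or {}
        s = np.ones(n)
        for j, name in enumerate(names):
            if chem.weights[j].any():
                if name not in signs:
                    raise ValueError(f"missing synaptic sign for presynaptic neuron {name!r}")
            s[j] = signs.get(name, 1)
        # conductance ratio between chemical and gap contacts (default 1)
        ratio = params.chem_conductance_pS / params.gap_conductance_pS
        M += ratio * (chem.weights.T * s[np.newaxis, :])

    if params.include_leak:
        M -= params.leak_ratio * np.eye(n)
    return names, M


def eigenmodes(
    M: np.ndarray, params: DynamicsParams | None = None, names: list[str] | None = None
) -> EigenAnalysis:
    """Full eigendecomposition with a deterministic sign/phase convention.

    Modes are L2-normalized and rotated so their largest-magnitude component
    is positive real.  Decay time of mode k is 1/|Re lambda_k| in units of
    tau (infinite for purely imaginary/zero eigenvalues).
    """
    M = np.asarray(M, dtype=float)
    symmetric = np.allclose(M, M.T)
    if symmetric:
        vals, vecs = np.linalg.eigh(M)
        vals = vals.astype(complex)
        vecs = vecs.astype(complex)
    else:
        vals, vecs = np.linalg.eig(M)
    order = np.argsort(-vals.real, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    # unit norm + phase convention
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    top = np.argmax(np.abs(vecs), axis=0)
    phases = vecs[top, np.arange(vecs.shape[1])]
    phases = phases / np.abs(phases)
    vecs = vecs / phases[np.newaxis, :]

    with np.errstate(divide="ignore"):
        decay = 1.0 / np.abs(vals.real)
    sparseness = np.abs(vecs).sum(axis=0)
    residuals = np.linalg.norm(M @ vecs - vecs * vals[np.newaxis, :], axis=0)
    return EigenAnalysis(
        names=names or [f"v{i}" for i in range(M.shape[0])],
        eigenvalues=vals,
        eigenmodes=vecs,
        decay_times_tau=decay,
        sparseness=sparseness,
        residuals=residuals,
    )


def simulate_response(
    M: np.ndarray,
    v0: np.ndarray,
    times: np.ndarray,
    params: DynamicsParams | None = None,
) -> np.ndarray:
    """Trajectory v(t) of dv/dt = (1/tau) M v, with times in units of tau.

    Uses the eigendecomposition when the eigenbasis is well-conditioned and
    falls back to dense matrix exponentials otherwise.
    """
    M = np.asarray(M, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be non-negative and ascending")
    vals, vecs = np.linalg.eig(M)
    cond = np.linalg.cond(vecs)
    if cond < 1e8:
        coeffs = np.linalg.solve(vecs, v0.astype(complex))
        traj = np.real(
            (vecs * coeffs[np.newaxis, :]) @ np.exp(np.outer(vals, times))
        ).T
    else:
        traj = np.empty((len(times), len(v0)))
        for k, t in enumerate(times):
            traj[k] = linalg.expm(M * t) @ v0
    return traj


def signal_flow_layout(chem: AdjacencyNetwork) -> dict[str, float]:
    """Vertical (signal-flow) coordinate per neuron.

    Minimizes sum over directed contacts w_ij (z_j - z_i - 1)^2; the
    stationarity condition is L_sym z = d_in - d_out on the symmetrized
    weights, solved per weakly-connected component under a zero-mean gauge.
    """
    if not chem.directed:
        raise ValueError("signal_flow_layout requires a directed network")
    W = chem.weights
    W_sym = W + W.T
    L = np.diag(W_sym.sum(axis=1)) - W_sym
    b = W.sum(axis=0) - W.sum(axis=1)  # d_in - d_out (weighted)
    z = np.zeros(chem.n)
    # solve per weak component with mean-zero gauge (L is singular)
    from scipy.sparse.csgraph import connected_components as _cc
    from scipy import sparse as _sp

    n_comp, labels = _cc(_sp.csr_matrix((W_sym > 0).astype(int)), directed=False)
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            continue
        sub = L[np.ix_(idx, idx)]
        zc, *_ = np.linalg.lstsq(sub, b[idx], rcond=None)
        z[idx] = zc - zc.mean()
    return dict(zip(chem.names, z))


def affinity_layout(combined: AdjacencyNetwork, normalized: bool = False) -> dict[str, tuple[float, float]]:
    """Planar coordinates from the 2nd and 3rd smallest Laplacian eigenmodes
    of the symmetrized weighted network, computed on the giant component."""
    W = combined.weights
    sym = AdjacencyNetwork(
        names=list(combined.names),
        weights=np.maximum(W, W.T) if combined.directed else W,
        directed=False,
        quantitation=combined.quantitation,
    )
    g = giant_component(sym)
    if g.n < 3:
        raise ValueError("affinity layout needs a giant component of at least 3 nodes")
    L = graph_laplacian(g)
    if normalized:
        d = np.clip(g.weights.sum(axis=1), 1e-12, None)
        Dinv = np.diag(1.0 / np.sqrt(d))
        L = Dinv @ L @ Dinv
    vals, vecs = np.linalg.eigh(L)
    xy = vecs[:, 1:3]
    # deterministic sign: largest-magnitude entry positive
    for col in range(2):
        j = np.argmax(np.abs(xy[:, col]))
        if xy[j, col] < 0:
            xy[:, col] = -xy[:, col]
    return {name: (float(x), float(y)) for name, (x, y) in zip(g.names, xy)}


def circuit_probability_bound(
    n: int, mode_sizes: list[int], k: int, n_circuits: int = 1
) -> float:
    """Union-bound probability that a random k-set of neurons lies inside the
    strong-neuron set of some eigenmode: min(1, n_circuits * sum C(m_i, k) / C(n, k))."""
    if k > n:
        raise ValueError("circuit size k cannot exceed n")
    if any(m > n for m in mode_sizes):
        raise ValueError("mode sizes cannot exceed n")
    total = math.comb(n, k)
    hits = sum(math.comb(m, k) for m in mode_sizes if m >= k)
    return min(1.0, n_circuits * hits / total)


def pseudospectrum(
    M: np.ndarray,
    re_range: tuple[float, float],
    im_range: tuple[float, float],
    resolution: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smallest singular value of (zI - M) over a complex-plane grid.

    The epsilon-pseudospectrum is the sublevel set sigma_min <= epsilon; for
    a normal matrix it equals the union of epsilon-disks around eigenvalues.
    Returns (re_grid, im_grid, sigma_min field).
    """
    M = np.asarray(M, dtype=complex)
    n = M.shape[0]
    res = np.linspace(re_range[0], re_range[1], resolution)
    ims = np.linspace(im_range[0], im_range[1], resolution)
    field_vals = np.empty((len(ims), len(res)))
    eye = np.eye(n)
    for a, im in enumerate(ims):
        for b, re in enumerate(res):
            z = complex(re, im)
            field_vals[a, b] = linalg.svdvals(z * eye - M)[-1]
    return res, ims, field_vals
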