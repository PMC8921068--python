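"""Per-state Markov information graphs and the multiplex model.

Each hidden state s defines a weighted directed graph over the D brain
regions: node weights are the state's mean activity a(s) = mu(s), and the
edge weight from region x to region y is the row-normalised absolute
correlation

    W(s)^{x,y} = |rho(s)^{x,y}| / sum_z |rho(s)^{x,z}|,

where rho(s) is the correlation matrix derived from the state covariance
Sigma(s). W(s) is therefore a row-stochastic Markov transition matrix over
regions — a model of probabilistic information flow in space — and the
per-state graphs are linked into a multiplex model by the state transition
matrix P in time. The denominator includes z = x, so every node keeps a
self-loop of weight 1/row-sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hmgm.containers import check_psd, check_row_stochastic
from hmgm.hmm_core import HMGModel, stationary_distribution


@dataclass
class StateGraph:
    """Weighted directed graph G(s) = (V, a(s), W(s)) for one state."""

    state_id: int
    nodes: list[str]
    a: np.ndarray  # node activities, = mu(s)
    W: np.ndarray  # row-stochastic edge weights

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.W = check_row_stochastic(np.asarray(self.W, dtype=float), name="W")
        D = self.W.shape[0]
        if self.a.size != D or len(self.nodes) != D:
            raise ValueError("node count mismatch between a, W and node names")
        if np.any(np.diag(self.W) <= 0):
            raise ValueError("W must keep positive self-loops (|rho|=1 on the diagonal)")

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph()
        for i, name in enumerate(self.nodes):
            G.add_node(name, activity=float(self.a[i]))
        for i in range(self.n_regions):
            for j in range(self.n_regions):
                if self.W[i, j] > 0:
                    G.add_edge(self.nodes[i], self.nodes[j], weight=float(self.W[i, j]))
        return G


@dataclass
class MultiplexModel:
    """State graphs (layers) linked by the interlayer transition matrix P.

    ``sigmas`` optionally carries the per-state region-space covariances; the
    graphs themselves only keep normalised |correlation| weights, but the
    functional-homogeneity scoring downstream needs the covariances.
    """

    state_graphs: list[StateGraph]
    P: np.ndarray
    pi: np.ndarray
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.P = check_row_stochastic(np.asarray(self.P, dtype=float), name="P")
        self.pi = np.asarray(self.pi, dtype=float)
        K = len(self.state_graphs)
        if self.P.shape[0] != K or self.pi.size != K:
            raise ValueError("state graph count must match dim(P) and dim(pi)")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if self.sigmas is not None:
            self.sigmas = np.asarray(self.sigmas, dtype=float)
            if self.sigmas.shape[0] != K:
                raise ValueError("need one covariance per state")

    @property
    def K(self) -> int:
        return len(self.state_graphs)


def markov_information_graph(
    mu: np.ndarray,
    sigma: np.ndarray,
    nodes: list[str] | None = None,
    state_id: int = 0,
    ridge: float = 1e-10,
) -> StateGraph:
    """Build G(s) from a state's back-projected mean and covariance.

    The correlation matrix is computed from ``sigma``; rank-deficient
    covariances (expected after back-projection from d < D dimensions) are
    handled by a small diagonal ridge before normalising, with a warning.
    A region with exactly zero variance has no defined correlations and is an
    error, reported by name.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.asarray(sigma, dtype=float)
    check_psd(sigma, name="sigma")
    D = sigma.shape[0]
    if nodes is None:
        nodes = [f"roi_{i:03d}" for i in range(D)]
    var = np.diag(sigma).copy()
    zero = np.flatnonzero(var <= 0)
    if zero.size:
        raise ValueError(f"zero-variance region(s), correlation undefined: {[nodes[i] for i in zero]}")
    if np.linalg.matrix_rank(sigma, tol=1e-10 * var.max()) < D:
        warnings.warn("rank-deficient covariance: correlations computed with ridge-regularised variances")
        sigma = sigma + np.eye(D) * ridge * var.max()
        var = np.diag(sigma)
    inv_sd = 1.0 / np.sqrt(var)
    rho = sigma * inv_sd[:, None] * inv_sd[None, :]
    np.fill_diagonal(rho, 1.0)
    absrho = np.abs(np.clip(rho, -1.0, 1.0))
    W = absrho / absrho.sum(axis=1, keepdims=True)
    return StateGraph(state_id=state_id, nodes=list(nodes), a=mu, W=W)


def symmetry_fraction(W: np.ndarray) -> float:
    """Fraction of the matrix energy carried by the symmetric part.

    Sym(W) = ||(W + W^T)/2||_F^2 / ||W||_F^2, in [0, 1]. Symmetric and
    antisymmetric parts are orthogonal under the Frobenius inner product, so
    the symmetric and antisymmetric fractions sum to one. Equals 1 exactly
    when W is symmetric and 0 when antisymmetric.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    total = float(np.sum(W * W))
    if total == 0.0:
        raise ValueError("symmetry fraction undefined for the zero matrix")
    S = (W + W.T) / 2.0
    return float(np.sum(S * S) / total)


def build_multiplex(model: HMGModel, nodes: list[str] | None = None) -> MultiplexModel:
    """Assemble the full multiplex model from a fitted HMM."""
    graphs = [
        markov_information_graph(model.mu[s], model.sigma[s], nodes=nodes, state_id=s)
        for s in range(model.K)
    ]
    pi = stationary_distribution(model.P)
    return MultiplexModel(state_graphs=graphs, P=model.P, pi=pi, sigmas=model.sigma)


def write_state_graph(graph: StateGraph, out_dir: str | Path) -> None:
    """Export one state graph as GraphML plus a delimited edge list."""
    import networkx as nx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph.to_networkx(), out / f"state_{graph.state_id:02d}.graphml")
    with open(out / f"state_{graph.state_id:02d}_edges.tsv", "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i in range(graph.n_regions):
            for j in range(graph.n_regions):
                if graph.W[i, j] > 0:
                    fh.write(f"{graph.nodes[i]}\t{graph.nodes[j]}\t{graph.W[i, j]:.10g}\n")


def write_multiplex(model: MultiplexModel, out_dir: str | Path) -> None:
    """Export all layers plus P and pi as delimited text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g in model.state_graphs:
        write_state_graph(g, out)
    np.savetxt(out / "transition_matrix.tsv", model.P, delimiter="\t")
    np.savetxt(out / "stationary_distribution.tsv", model.pi, delimiter="\t")
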