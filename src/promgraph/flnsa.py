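"""Sample-similarity graph via the fast linear neighborhood similarity approach.

Each sample row x_i of the nonnegative feature matrix X (m x l) is
approximated as a nonnegative linear combination of its k nearest
neighbors.  The learned reconstruction weights W minimise

    (1/2) ||X - (C*W) X||_F^2 + (mu/2) ||(C*W) e - e||^2

subject to W >= 0 and support(W) within support(C), where C is the binary
k-nearest-neighbor indicator (zero diagonal), * the Hadamard product, and
e the all-ones vector; the soft penalty pushes each neighbor-weight row to
sum to 1.  The minimiser is found by a seeded multiplicative update

    W_ij <- W_ij * (X X^T + mu e e^T)_ij / ((C*W) X X^T + mu (C*W) e e^T)_ij

on neighbor entries only.  The symmetrised support of W defines the
weighted sample graph; if that graph is disconnected, a mutual-kNN
backbone plus nearest-pair bridges is unioned in so every downstream
embedding sees a single component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

_EPS = 1e-12  # denominator floor for the multiplicative update


@dataclass
class NeighborIndicator:
    """Binary kNN indicator C: row i marks the k nearest other rows."""

    C: np.ndarray
    neighborhood_ratio: float
    k: int


@dataclass
class ReconstructionWeights:
    """Learned nonnegative reconstruction weights and convergence state."""

    W: np.ndarray
    mu: float
    iterations_run: int
    converged: bool


@dataclass
class SequenceGraph:
    """Connected, symmetric, zero-diagonal weighted graph over samples.

    ``provenance`` tags each undirected edge (i < j) as coming from the
    similarity weights (``"flnsa"``) or from the connectivity repair
    (``"connectivity_backbone"``).
    """

    adjacency: np.ndarray
    provenance: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency)
        for (i, j), tag in self.provenance.items():
            g.edges[i, j]["provenance"] = tag
        return g

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\tweight\tprovenance\n")
            ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
            for i, j in zip(ii.tolist(), jj.tolist()):
                tag = self.provenance.get((i, j), "flnsa")
                fh.write(f"{i}\t{j}\t{self.adjacency[i, j]:.10g}\t{tag}\n")


def neighbor_indicator(X: np.ndarray, neighborhood_ratio: float = 0.1) -> NeighborIndicator:
    """kNN indicator by Euclidean distance, k = max(1, round(ratio*(m-1))).

    Ties are broken toward the smaller index; the diagonal is always zero.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples")
    if not 0 < neighborhood_ratio < 1:
        raise ValueError("neighborhood_ratio must be in (0, 1)")
    k = max(1, int(np.round(neighborhood_ratio * (m - 1))))
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    # stable argsort on distance gives the smaller-index tie-break
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    C = np.zeros((m, m))
    C[np.repeat(np.arange(m), k), order.ravel()] = 1.0
    return NeighborIndicator(C=C, neighborhood_ratio=neighborhood_ratio, k=k)


def flnsa_objective(
    X: np.ndarray, C: np.ndarray, W: np.ndarray, mu: float
) -> float:
    """Literal objective value: reconstruction error + row-sum penalty."""
    CW = C * W
    recon = X - CW @ X
    rowsum_dev = CW.sum(axis=1) - 1.0
    return 0.5 * float(np.sum(recon**2)) + 0.5 * mu * float(np.sum(rowsum_dev**2))


def flnsa_fit(
    X: np.ndarray,
    C: NeighborIndicator | np.ndarray,
    mu: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    callback=None,
) -> ReconstructionWeights:
    """Learn W by seeded multiplicative updates on the neighbor support.

    W starts uniform(0, 1] on support(C) and stays nonnegative throughout;
    iteration stops when the max absolute elementwise change drops below
    ``tol`` or after ``max_iter`` sweeps.  ``callback(iteration, W)``, if
    given, is invoked after every update so invariants and the objective
    can be traced.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be nonnegative for the multiplicative update")
    Cmat = C.C if isinstance(C, NeighborIndicator) else np.asarray(C, dtype=float)
    m = X.shape[0]
    if Cmat.shape != (m, m):
        raise ValueError("C shape must match X rows")
    rng = np.random.default_rng(seed)
    support = Cmat > 0
    W = np.zeros((m, m))
    W[support] = 1.0 - rng.random(int(support.sum()))  # uniform on (0, 1]

    G = X @ X.T                                   # gram matrix, computed once
    numer = G + mu                                # (X X^T + mu e e^T)
    rows, cols = np.nonzero(support)
    use_sparse = m >= 100
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if use_sparse:
            CW = sp.csr_matrix((W[rows, cols], (rows, cols)), shape=(m, m))
            denom_full = CW @ G + mu * np.asarray(CW.sum(axis=1)).reshape(-1, 1)
        else:
            CW = Cmat * W
            denom_full = CW @ G + mu * CW.sum(axis=1, keepdims=True)
        W_new = np.zeros_like(W)
        ratio = numer[rows, cols] / (denom_full[rows, cols] + _EPS)
        W_new[rows, cols] = W[rows, cols] * ratio
        delta = np.abs(W_new - W).max()
        W = W_new
        if callback is not None:
            callback(it, W)
        if delta < tol:
            converged = True
            break
    return ReconstructionWeights(W=W, mu=mu, iterations_run=it, converged=converged)


def _bridge_components(adj: np.ndarray, X: np.ndarray, floor_weight: float,
                       provenance: dict[tuple[int, int], str]) -> np.ndarray:
    """Join components by linking nearest inter-component sample pairs."""
    while True:
        n_comp, labels = connected_components(sp.csr_matrix(adj), directed=False)
        if n_comp == 1:
            return adj
        dist = cdist(X, X)
        same = labels[:, None] == labels[None, :]
        dist[same] = np.inf
        # bridge component of node 0 to its globally nearest outside pair
        comp0 = labels == labels[0]
        sub = dist[comp0][:, ~comp0]
        i_loc, j_loc = np.unravel_index(np.argmin(sub), sub.shape)
        i = np.flatnonzero(comp0)[i_loc]
        j = np.flatnonzero(~comp0)[j_loc]
        adj[i, j] = adj[j, i] = max(adj[i, j], floor_weight)
        provenance[(min(i, j), max(i, j))] = "connectivity_backbone"


def build_graph(
    W: ReconstructionWeights | np.ndarray,
    backbone_c: int = 3,
    X: np.ndarray | None = None,
    min_edge_weight: float = 0.0,
) -> SequenceGraph:
    """Symmetrise W into a connected weighted graph.

    Adjacency is elementwise max(W, W^T) with zero diagonal. If that graph
    is disconnected, a mutual-kNN backbone (each node to its ``backbone_c``
    nearest samples by Euclidean distance on X, at a small floor weight)
    is unioned in, followed by nearest-pair bridging until one component
    remains. ``min_edge_weight`` optionally zeroes weaker similarity edges
    first.
    """
    Wmat = W.W if isinstance(W, ReconstructionWeights) else np.asarray(W, dtype=float)
    m = Wmat.shape[0]
    adj = np.maximum(Wmat, Wmat.T)
    if min_edge_weight > 0:
        adj[adj < min_edge_weight] = 0.0
    np.fill_diagonal(adj, 0.0)
    provenance: dict[tuple[int, int], str] = {}
    for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
        provenance[(int(i), int(j))] = "flnsa"

    n_comp, _ = connected_components(sp.csr_matrix(adj), directed=False)
    if n_comp > 1:
        if X is None:
            raise ValueError("X is required to repair a disconnected graph")
        if not 0 < backbone_c < m:
            raise ValueError("backbone_c must satisfy 0 < c < m")
        positive = adj[adj > 0]
        floor_weight = float(positive.min()) if positive.size else 1e-6
        dist = cdist(X, X)
        np.fill_diagonal(dist, np.inf)
        nearest = np.argsort(dist, axis=1, kind="stable")[:, :backbone_c]
        for i in range(m):
            for j in nearest[i]:
                j = int(j)
                if adj[i, j] == 0:
                    adj[i, j] = adj[j, i] = floor_weight
                    provenance[(min(i, j), max(i, j))] = "connectivity_backbone"
        adj = _bridge_components(adj, np.asarray(X, dtype=float), floor_weight, provenance)
    return SequenceGraph(adjacency=adj, provenance=provenance)


class FLNSA(BaseEstimator):
    """Estimator facade: features in, connected similarity graph out.

    Transductive by design — the graph is built over every sample handed to
    :meth:`fit` (train and test rows together), matching the protocol in
    which only the downstream classifier respects the train/test split.

    Parameters
    ----------
    neighborhood_ratio : fraction of the other m-1 samples treated as
        neighbors (k = max(1, round(ratio*(m-1)))).
    mu : weight of the soft row-sum-to-1 penalty.
    tol, max_iter : multiplicative-update stopping rule.
    backbone_c : nearest-sample count for connectivity repair.
    min_edge_weight : optional threshold zeroing weak similarity edges.
    """

    def __init__(
        self,
        neighborhood_ratio: float = 0.1,
        mu: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        backbone_c: int = 3,
        min_edge_weight: float = 0.0,
        seed: int = 0,
    ):
        self.neighborhood_ratio = neighborhood_ratio
        self.mu = mu
        self.tol = tol
        self.max_iter = max_iter
        self.backbone_c = backbone_c
        self.min_edge_weight = min_edge_weight
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.indicator_ = neighbor_indicator(X, self.neighborhood_ratio)
        self.weights_ = flnsa_fit(
            X, self.indicator_, self.mu, self.tol, self.max_iter, self.seed
        )
        self.graph_ = build_graph(
            self.weights_, self.backbone_c, X, self.min_edge_weight
        )
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the symmetric adjacency matrix."""
        return self.fit(X).graph_.adjacency
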