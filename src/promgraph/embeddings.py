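"""Multi-scale node embeddings over the sample-similarity graph.

Three complementary scales are embedded and concatenated:

* **node** — second-order biased random walks (return parameter p, in-out
  parameter q) fed to a skip-gram-with-negative-sampling model, capturing a
  node's immediate interaction neighborhood;
* **community** — the leading eigenvectors of the weighted modularity
  matrix B = A - d d^T / (2 W_tot), exposing mesoscale community
  structure;
* **global** — truncated SVD factors of positive log-shifted k-step
  transition matrices S^t (S = D^-1 A), one block per step t = 1..K,
  capturing long-range similarity.

All three honour edge weights and are deterministic under a fixed seed
(eigenvector and singular-vector signs are fixed by making each column's
largest-magnitude entry positive).  The skip-gram trainer is a compact
vectorised NumPy implementation of SGNS with a linearly decaying learning
rate and unigram^0.75 negative sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .flnsa import SequenceGraph

SCALE_ORDER = ("node", "community", "global")


@dataclass
class WalkCorpus:
    """Random walks over graph nodes, one list of node indices per walk."""

    walks: list[list[int]]
    p: float
    q: float
    walks_per_node: int
    walk_length: int
    seed: int


@dataclass
class EmbeddingMatrix:
    """m x d node vectors with a scale tag and stable column names."""

    vectors: np.ndarray
    scale_tag: str
    column_names: list[str]

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def _as_adjacency(graph) -> np.ndarray:
    if isinstance(graph, SequenceGraph):
        return graph.adjacency
    return np.asarray(graph, dtype=float)


def _named(vectors: np.ndarray, scale_tag: str) -> EmbeddingMatrix:
    names = [f"GraphEmbeddings_{k}" for k in range(vectors.shape[1])]
    return EmbeddingMatrix(vectors=vectors, scale_tag=scale_tag, column_names=names)


def _fix_signs(mat: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(mat), axis=0)
    signs = np.sign(mat[idx, np.arange(mat.shape[1])])
    signs[signs == 0] = 1.0
    return mat * signs


# ---------------------------------------------------------------- node scale


def generate_biased_walks(
    graph,
    p: float = 1.0,
    q: float = 1.0,
    walks_per_node: int = 10,
    walk_length: int = 40,
    seed: int = 0,
) -> WalkCorpus:
    """Second-order biased random walks on the weighted graph.

    From current node v with previous node t, the unnormalised weight of
    stepping to neighbor x is w(v,x)/p if x == t, w(v,x) if x is adjacent
    to t, and w(v,x)/q otherwise; the first step is proportional to edge
    weight alone.
    """
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    adj = _as_adjacency(graph)
    m = adj.shape[0]
    neighbors = [np.flatnonzero(adj[v]) for v in range(m)]
    weights = [adj[v, neighbors[v]] for v in range(m)]
    neighbor_sets = [set(nb.tolist()) for nb in neighbors]
    rng = np.random.default_rng(seed)
    walks: list[list[int]] = []
    for _ in range(walks_per_node):
        for start in range(m):
            walk = [start]
            for _step in range(walk_length - 1):
                v = walk[-1]
                nb = neighbors[v]
                if nb.size == 0:
                    break
                w = weights[v].copy()
                if len(walk) >= 2:
                    t = walk[-2]
                    t_nbrs = neighbor_sets[t]
                    for ci, x in enumerate(nb):
                        if x == t:
                            w[ci] /= p
                        elif x not in t_nbrs:
                            w[ci] /= q
                cum = np.cumsum(w)
                walk.append(int(nb[np.searchsorted(cum, rng.random() * cum[-1])]))
            walks.append(walk)
    return WalkCorpus(
        walks=walks, p=p, q=q, walks_per_node=walks_per_node,
        walk_length=walk_length, seed=seed,
    )


def _scatter_sub(target: np.ndarray, indices: np.ndarray, updates: np.ndarray) -> None:
    """target[indices] -= updates with duplicate-index accumulation."""
    n = indices.shape[0]
    sel = sp.csr_matrix(
        (np.ones(n, dtype=updates.dtype), (indices, np.arange(n))),
        shape=(target.shape[0], n),
    )
    target -= sel @ updates


def _walk_pairs(walks: list[list[int]], window: int) -> np.ndarray:
    """All (center, context) pairs within the symmetric window."""
    pairs = []
    for walk in walks:
        arr = np.asarray(walk)
        n = len(arr)
        for offset in range(1, window + 1):
            if n <= offset:
                continue
            left = arr[:-offset]
            right = arr[offset:]
            pairs.append(np.column_stack([left, right]))
            pairs.append(np.column_stack([right, left]))
    return np.concatenate(pairs, axis=0)


def skipgram_embed(
    corpus: WalkCorpus,
    n_nodes: int | None = None,
    dim: int = 64,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Train skip-gram with negative sampling on the walk corpus.

    Walks are treated as sentences; each (center, context) co-occurrence
    within ``window`` is a positive pair, countered by ``negative`` draws
    from the unigram^0.75 node distribution.  Mini-batched SGD with a
    learning rate decaying linearly to lr/100; fully deterministic given
    the seed.
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_nodes is None:
        n_nodes = max(max(w) for w in corpus.walks) + 1
    rng = np.random.default_rng(seed)
    # float32 throughout: the SGD is bandwidth-bound and tolerance-free
    W_in = ((rng.random((n_nodes, dim)) - 0.5) / dim).astype(np.float32)
    W_out = np.zeros((n_nodes, dim), dtype=np.float32)

    counts = np.bincount(
        np.concatenate([np.asarray(w) for w in corpus.walks]), minlength=n_nodes
    ).astype(float)
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    pairs = _walk_pairs(corpus.walks, window)
    n_pairs = pairs.shape[0]
    # cap per-node repetition within a batch: summed gradients of a node
    # recurring too often in one stale-parameter batch overshoot and diverge
    batch = int(min(4096, max(256, 8 * n_nodes)))
    total_steps = epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    lr_min = lr / 100.0
    for _epoch in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            sel = pairs[order[lo : lo + batch]]
            centers, contexts = sel[:, 0], sel[:, 1]
            b = centers.shape[0]
            negs = np.searchsorted(noise_cdf, rng.random((b, negative)))
            cur_lr = lr + (lr_min - lr) * (step / max(total_steps - 1, 1))
            step += 1

            v = W_in[centers]                               # b x d
            targets = np.concatenate([contexts[:, None], negs], axis=1)  # b x (1+neg)
            u = W_out[targets]                              # b x (1+neg) x d
            scores = np.einsum("bkd,bd->bk", u, v)
            sig = 1.0 / (1.0 + np.exp(-np.clip(scores, -30, 30)))
            sig[:, 0] -= 1.0
            g = sig * np.float32(cur_lr)                    # b x (1+neg)
            grad_v = np.einsum("bk,bkd->bd", g, u)
            grad_u = (g[..., None] * v[:, None, :]).reshape(-1, dim)
            _scatter_sub(W_in, centers, grad_v)
            _scatter_sub(W_out, targets.ravel(), grad_u)
    return _named(W_in.astype(np.float64), "node")


# ----------------------------------------------------------- community scale


def modularity_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Weighted modularity matrix B = A - d d^T / (2 W_tot)."""
    A = np.asarray(adjacency, dtype=float)
    d = A.sum(axis=1)
    two_w = d.sum()
    return A - np.outer(d, d) / two_w


def socdim_embed(graph, k: int = 16) -> EmbeddingMatrix:
    """Top-k eigenvectors of the modularity matrix as community coordinates."""
    A = _as_adjacency(graph)
    m = A.shape[0]
    if not 1 <= k < m:
        raise ValueError("need 1 <= k < number of nodes")
    B = modularity_matrix(A)
    eigvals, eigvecs = np.linalg.eigh(B)
    top = np.argsort(eigvals)[::-1][:k]
    return _named(_fix_signs(eigvecs[:, top]), "community")


# -------------------------------------------------------------- global scale


def grarep_embed(
    graph,
    max_step: int = 4,
    dim_per_step: int = 16,
    log_shift: float | None = None,
) -> EmbeddingMatrix:
    """k-step transition-matrix factorisation (global scale).

    For each step t, the row-stochastic transition matrix S = D^-1 A is
    powered to S^t, shifted to Y = max(log(S^t_ij / colsum_j) - log(1/m), 0)
    and factored by truncated SVD; the sqrt-singular-value-scaled left
    factors of all K steps are concatenated.  ``log_shift`` overrides the
    default 1/m baseline.
    """
    A = _as_adjacency(graph)
    m = A.shape[0]
    if max_step < 1 or dim_per_step < 1:
        raise ValueError("max_step and dim_per_step must be >= 1")
    deg = A.sum(axis=1)
    if (deg == 0).any():
        raise ValueError("graph has isolated nodes; expected a connected graph")
    S = A / deg[:, None]
    baseline = log_shift if log_shift is not None else 1.0 / m
    blocks = []
    St = np.eye(m)
    for _t in range(1, max_step + 1):
        St = St @ S
        col = St.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            Y = np.log(St / col) - np.log(baseline)
        Y[~np.isfinite(Y)] = 0.0
        Y[Y < 0] = 0.0
        U, sing, _ = np.linalg.svd(Y, full_matrices=False)
        d_eff = min(dim_per_step, int(np.sum(sing > 1e-12)))
        block = np.zeros((m, dim_per_step))
        if d_eff > 0:
            block[:, :d_eff] = _fix_signs(U[:, :d_eff] * np.sqrt(sing[:d_eff]))
        blocks.append(block)
    return _named(np.concatenate(blocks, axis=1), "global")


# -------------------------------------------------------------- combination


def concat_embeddings(parts: list[EmbeddingMatrix]) -> EmbeddingMatrix:
    """Concatenate embeddings columnwise in canonical node/community/global order."""
    if not parts:
        raise ValueError("parts must be non-empty")
    rows = {p.vectors.shape[0] for p in parts}
    if len(rows) != 1:
        raise ValueError(f"row-count mismatch across parts: {sorted(rows)}")
    ordered = sorted(parts, key=lambda p: SCALE_ORDER.index(p.scale_tag))
    mat = np.concatenate([p.vectors for p in ordered], axis=1)
    return _named(mat, "combined")


class MultiScaleEmbedder:
    """Fit-transform facade producing the combined multi-scale embedding.

    ``scales`` selects any subset of {"node", "community", "global"}; an
    empty tuple yields a zero-width matrix (the "before graph embedding"
    ablation arm).
    """

    def __init__(
        self,
        scales: tuple[str, ...] = SCALE_ORDER,
        node_dim: int = 64,
        p: float = 1.0,
        q: float = 1.0,
        walks_per_node: int = 10,
        walk_length: int = 40,
        window: int = 5,
        epochs: int = 5,
        negative: int = 5,
        community_k: int = 16,
        global_max_step: int = 4,
        global_dim_per_step: int = 16,
        seed: int = 0,
    ):
        self.scales = tuple(scales)
        self.node_dim = node_dim
        self.p = p
        self.q = q
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.epochs = epochs
        self.negative = negative
        self.community_k = community_k
        self.global_max_step = global_max_step
        self.global_dim_per_step = global_dim_per_step
        self.seed = seed

    def fit_transform(self, graph) -> EmbeddingMatrix:
        adj = _as_adjacency(graph)
        m = adj.shape[0]
        parts: list[EmbeddingMatrix] = []
        if "node" in self.scales:
            corpus = generate_biased_walks(
                adj, self.p, self.q, self.walks_per_node, self.walk_length,
                seed=self.seed,
            )
            parts.append(
                skipgram_embed(
                    corpus, n_nodes=m, dim=self.node_dim, window=self.window,
                    epochs=self.epochs, negative=self.negative, seed=self.seed + 1,
                )
            )
        if "community" in self.scales:
            parts.append(socdim_embed(adj, k=min(self.community_k, m - 1)))
        if "global" in self.scales:
            parts.append(
                grarep_embed(adj, self.global_max_step, self.global_dim_per_step)
            )
        if not parts:
            return _named(np.zeros((m, 0)), "combined")
        self.embedding_ = concat_embeddings(parts)
        return self.embedding_
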