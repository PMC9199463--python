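"""Shared-nearest-neighbor graph construction and Louvain clustering.

Cells are connected by the Jaccard similarity of their k-nearest-neighbor
sets in PC space (each set includes the cell itself), edges below a prune
threshold are dropped, and communities are found by greedy Louvain
modularity optimization with a resolution parameter gamma scaling the
null-model term:

    Q(gamma) = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / (2m)] delta(c_i, c_j)

The node sweep order is shuffled by the seed; a local move is accepted only
if it improves Q by more than 1e-10; aggregation repeats until no
improvement. Modularity is recorded after every pass and asserted
non-decreasing. Exact neighbor search is used (desk scale), with distance
ties broken by lower cell index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .preprocess import Embedding

__all__ = ["SnnGraph", "ClusterLabels", "knn", "snn_jaccard", "louvain", "modularity"]

MOVE_EPS = 1e-10


@dataclass
class SnnGraph:
    """Undirected weighted cell graph; weights in (0, 1], no self-loops."""

    weights: sparse.csr_matrix

    def __post_init__(self) -> None:
        w = sparse.csr_matrix(self.weights)
        if w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        diff = (w - w.T).tocoo()
        if diff.nnz and np.abs(diff.data).max() > 1e-12:
            raise ValueError("adjacency must be symmetric")
        if w.diagonal().any():
            raise ValueError("self-loops not allowed")
        if w.nnz and ((w.data <= 0).any() or w.data.max() > 1 + 1e-12):
            raise ValueError("weights must lie in (0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ClusterLabels:
    """Per-cell cluster IDs: contiguous ints from 0, decreasing cluster size."""

    labels: np.ndarray
    modularity_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster IDs must be contiguous from 0")
        sizes = np.bincount(self.labels)
        if np.any(np.diff(sizes) > 0):
            raise ValueError("cluster IDs must be ordered by decreasing size")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.where(self.labels == cluster)[0]


def knn(embedding: Embedding | np.ndarray, k: int = 20) -> np.ndarray:
    """k-nearest-neighbor sets in PC space (Euclidean, exact).

    Returns an (n_cells, k) int array: each row is the cell itself plus its
    k-1 nearest others, sorted ascending. Distance ties break toward the
    lower cell index.
    """
    X = embedding.scores if isinstance(embedding, Embedding) else np.asarray(embedding, float)
    n = X.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"k={k} must satisfy 1 <= k < n_cells={n}")
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.maximum(d2, 0, out=d2)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        row = d2[i].copy()
        row[i] = np.inf                       # self is forced in separately
        order = np.lexsort((idx, row))        # distance, then lower index
        members = np.concatenate(([i], order[: k - 1]))
        out[i] = np.sort(members)
    return out


def snn_jaccard(neighbors: np.ndarray, prune: float = 1 / 15) -> SnnGraph:
    """SNN graph weighted by Jaccard similarity of neighbor sets.

    weight(i, j) = |N_i & N_j| / |N_i | N_j|; edges with weight < prune are
    removed.
    """
    n, k = neighbors.shape
    rows = np.repeat(np.arange(n), k)
    M = sparse.csr_matrix(
        (np.ones(n * k), (rows, neighbors.ravel())), shape=(n, n)
    )
    inter = (M @ M.T).tocoo()
    union = 2 * k - inter.data
    w = inter.data / union
    keep = (w >= prune) & (inter.row != inter.col)
    adj = sparse.csr_matrix((w[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))
    return SnnGraph(adj)


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

def modularity(adj: sparse.spmatrix, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Q(gamma) over ordered node pairs of the (symmetric) adjacency.

    Self-loop entries A_ii, if present (aggregated graphs), count once.
    """
    A = sparse.csr_matrix(adj)
    labels = np.asarray(labels)
    k = np.asarray(A.sum(axis=1)).ravel()
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    coo = A.tocoo()
    same = labels[coo.row] == labels[coo.col]
    a_term = coo.data[same].sum()
    k_term = sum(
        k[labels == c].sum() ** 2 for c in np.unique(labels)
    )
    return float(a_term / two_m - resolution * k_term / two_m**2)


def _louvain_level(
    adj_list: list[dict[int, float]],
    self_w: np.ndarray,
    k: np.ndarray,
    two_m: float,
    resolution: float,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """One phase-1 sweep-to-convergence. Returns community assignment, or
    None if no node moved."""
    n = len(adj_list)
    comm = np.arange(n)
    sigma_tot = k.copy().astype(float)
    order = rng.permutation(n)
    moved_any = False
    improved = True
    while improved:
        improved = False
        for v in order:
            cv = comm[v]
            # weights from v to each neighboring community
            w_to: dict[int, float] = {}
            for u, w in adj_list[v].items():
                w_to[comm[u]] = w_to.get(comm[u], 0.0) + w
            sigma_tot[cv] -= k[v]
            base = w_to.get(cv, 0.0) - resolution * k[v] * sigma_tot[cv] / two_m
            best_c, best_g = cv, base
            for d in sorted(w_to):   # sorted: gain ties keep the lowest id
                if d == cv:
                    continue
                g = w_to[d] - resolution * k[v] * sigma_tot[d] / two_m
                if g > best_g:
                    best_c, best_g = d, g
            # accept only if dQ = 2*(best_g - base)/(2m) > MOVE_EPS
            if best_c != cv and 2 * (best_g - base) / two_m > MOVE_EPS:
                comm[v] = best_c
                sigma_tot[best_c] += k[v]
                improved = True
                moved_any = True
            else:
                comm[v] = cv
                sigma_tot[cv] += k[v]
    return comm if moved_any else None


def _aggregate(
    adj_list: list[dict[int, float]], self_w: np.ndarray, comm: np.ndarray
) -> tuple[list[dict[int, float]], np.ndarray, np.ndarray]:
    uniq, new = np.unique(comm, return_inverse=True)
    nc = len(uniq)
    new_self = np.zeros(nc)
    new_adj: list[dict[int, float]] = [dict() for _ in range(nc)]
    for v, nbrs in enumerate(adj_list):
        cv = new[v]
        new_self[cv] += self_w[v]
        for u, w in nbrs.items():
            cu = new[u]
            if cu == cv:
                if u > v:
                    new_self[cv] += 2 * w   # ordered pairs: (u,v) and (v,u)
            else:
                new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
    return new_adj, new_self, new


def louvain(graph: SnnGraph, resolution: float = 0.5, seed: int = 0) -> ClusterLabels:
    """Louvain community detection at resolution gamma.

    Deterministic given ``seed``. Disconnected components (including
    isolated nodes) are handled naturally — no edge ever merges them.
    Modularity after each pass is recorded in ``modularity_trace`` and
    asserted non-decreasing.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    A = graph.weights
    rng = np.random.default_rng(seed)

    coo = A.tocoo()
    adj_list: list[dict[int, float]] = [dict() for _ in range(n)]
    for i, j, w in zip(coo.row, coo.col, coo.data):
        if i != j:
            adj_list[i][j] = adj_list[i].get(j, 0.0) + w
    self_w = np.zeros(n)
    k = self_w + np.array([sum(d.values()) for d in adj_list])
    two_m = float(k.sum())

    assignment = np.arange(n)          # fine nodes -> current supernode
    trace: list[float] = []
    if two_m == 0:
        labels = np.arange(n)
        trace = [0.0]
    else:
        q_prev = -np.inf
        while True:
            comm = _louvain_level(adj_list, self_w, k, two_m, resolution, rng)
            if comm is None:
                break
            adj_list, self_w, new = _aggregate(adj_list, self_w, comm)
            assignment = new[assignment]   # `new` maps current node -> compact community
            k = self_w + np.array([sum(d.values()) for d in adj_list])
            q = modularity(A, assignment, resolution)
            if q < q_prev - 1e-9:
                raise AssertionError(
                    f"modularity decreased across passes: {q_prev} -> {q}"
                )
            trace.append(q)
            q_prev = q
            if len(adj_list) == 1:
                break
        labels = assignment
        if not trace:
            trace = [modularity(A, labels, resolution)]

    # contiguous IDs ordered by decreasing size; ties by smallest member index
    uniq, inv = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inv)
    first = np.full(len(uniq), n)
    for i, c in enumerate(inv):
        first[c] = min(first[c], i)
    order = sorted(range(len(uniq)), key=lambda c: (-sizes[c], first[c]))
    rank = np.empty(len(uniq), dtype=int)
    rank[order] = np.arange(len(uniq))
    final = rank[inv]
    return ClusterLabels(final, modularity_trace=trace)
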