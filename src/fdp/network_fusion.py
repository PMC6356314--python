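"""Fuse per-time-point active PPI networks by kernel cross-diffusion.

Each active network's edges are first weighted by an exponential transform of
the edge clustering coefficient (ECC), the triangle density of the edge. From
the weight matrix W two kernels are derived: the *full* kernel P, a
row-stochastic matrix carrying each gene's similarity to all others, and the
*KNN* kernel S, restricted to each gene's K strongest graph neighbors. Pairs
of networks are then fused by cross-diffusion — each P is repeatedly pushed
through the other network's S — and averaged; hierarchical agglomeration by
Frobenius distance of the W matrices merges all time points into one matrix.

All matrices are aligned to the union of active node sets across time points
(the genes active at at least one time point); a node inactive at a given time
point has an all-zero W row there and a degenerate unit-diagonal kernel row,
making it a neutral fixed point of diffusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ActiveNetwork",
    "FusedNetwork",
    "edge_clustering_coefficient",
    "edge_weight",
    "weight_matrix",
    "align_active_networks",
    "full_kernel",
    "knn_kernel",
    "network_distance",
    "diffuse_pair",
    "fuse_pair",
    "fuse_all",
]


@dataclass(frozen=True)
class ActiveNetwork:
    """Time point ``time_index``'s ECC-weighted adjacency, union-aligned.

    ``W`` is symmetric, non-negative, zero on the diagonal, with all-zero rows
    for nodes inactive at this time point.
    """

    time_index: int
    node_ids: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self) -> None:
        W = self.W
        n = len(self.node_ids)
        if W.shape != (n, n):
            raise ValueError(f"W shape {W.shape} does not match {n} node ids")


@dataclass(frozen=True)
class FusedNetwork:
    """Result of hierarchical pairwise diffusion over all active networks."""

    node_ids: tuple[str, ...]
    R: np.ndarray
    fusion_order: tuple[tuple[str, str], ...]


def edge_clustering_coefficient(graph: nx.Graph, u, v) -> float:
    """ECC(u, v) = |N(u) ∩ N(v)| / min(deg(u) - 1, deg(v) - 1).

    Counts the triangles the edge participates in against the maximum possible
    given its endpoint degrees. A degree-1 endpoint admits no triangle, so the
    degenerate denominator 0 yields ECC = 0.
    """
    if not graph.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge")
    common = len(set(graph[u]) & set(graph[v]))
    denom = min(graph.degree(u) - 1, graph.degree(v) - 1)
    if denom <= 0:
        return 0.0
    return common / denom


def edge_weight(graph: nx.Graph, u, v, mu: float = 0.5) -> float:
    """Exponential ECC edge weight exp(ECC(u,v) / (mu * eps)).

    eps is the local ECC scale: the mean of (mean ECC of u to its neighbors,
    mean ECC of v to its neighbors, ECC(u,v)). When eps = 0 — no clustering
    evidence anywhere around the edge — the weight is the neutral 1.
    """
    if not graph.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge")
    ecc_uv = edge_clustering_coefficient(graph, u, v)
    mean_u = float(
        np.mean([edge_clustering_coefficient(graph, u, w) for w in graph[u]])
    )
    mean_v = float(
        np.mean([edge_clustering_coefficient(graph, v, w) for w in graph[v]])
    )
    eps = (mean_u + mean_v + ecc_uv) / 3.0
    if eps == 0.0:
        return 1.0
    return float(np.exp(ecc_uv / (mu * eps)))


def weight_matrix(
    graph: nx.Graph, node_ids: Sequence[str], mu: float = 0.5
) -> np.ndarray:
    """ECC-weight adjacency of ``graph`` aligned to ``node_ids``.

    Equivalent to calling :func:`edge_weight` per edge, but computes every
    edge's ECC once and reuses the per-node neighbor means.
    """
    index = {g: i for i, g in enumerate(node_ids)}
    n = len(node_ids)
    W = np.zeros((n, n))
    if graph.number_of_edges() == 0:
        return W
    ecc = {}
    for u, v in graph.edges:
        ecc[(u, v)] = ecc[(v, u)] = edge_clustering_coefficient(graph, u, v)
    node_mean = {
        u: float(np.mean([ecc[(u, w)] for w in graph[u]])) if graph.degree(u) else 0.0
        for u in graph.nodes
    }
    for u, v in graph.edges:
        e = (node_mean[u] + node_mean[v] + ecc[(u, v)]) / 3.0
        w = 1.0 if e == 0.0 else float(np.exp(ecc[(u, v)] / (mu * e)))
        i, j = index[u], index[v]
        W[i, j] = W[j, i] = w
    return W


def align_active_networks(
    graphs: Sequence[nx.Graph], mu: float = 0.5
) -> list[ActiveNetwork]:
    """Weight each time point's graph and align all to the union node set."""
    union = sorted(set().union(*(g.nodes for g in graphs)) if graphs else set())
    node_ids = tuple(union)
    return [
        ActiveNetwork(time_index=t, node_ids=node_ids, W=weight_matrix(g, node_ids, mu))
        for t, g in enumerate(graphs, start=1)
    ]


def _degenerate_rows(W: np.ndarray) -> np.ndarray:
    return W.sum(axis=1) == 0.0


def full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-stochastic full kernel P: off-diagonal w(u,v)/(2*sum), diagonal 1/2.

    The row sum excludes the diagonal, so the kernel of a fused matrix reuses
    this function unchanged. Rows of isolated nodes become unit diagonal rows.
    """
    W = np.asarray(W, dtype=float)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    sums = off.sum(axis=1)
    isolated = sums == 0.0
    safe = np.where(isolated, 1.0, sums)
    P = off / (2.0 * safe[:, None])
    np.fill_diagonal(P, 0.5)
    P[isolated, :] = 0.0
    P[isolated, np.flatnonzero(isolated)] = 1.0
    return P


def knn_kernel(W: np.ndarray, K: int = 20) -> np.ndarray:
    """KNN kernel S: each row keeps its K largest-weight graph neighbors.

    Kept entries are w(u,v)/(2 * sum over kept), so each connected row sums to
    1/2; everything outside the top-K support is exactly zero. Ties among
    equal weights keep the lexicographically smallest node ids — rows are
    aligned to sorted ids, so index order is lexicographic order. Isolated
    rows become unit diagonal rows.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    S = np.zeros_like(W)
    for i in range(n):
        row = W[i].copy()
        row[i] = 0.0
        nbrs = np.flatnonzero(row > 0.0)
        if nbrs.size == 0:
            S[i, i] = 1.0
            continue
        # stable sort on descending weight keeps ascending index among ties
        order = nbrs[np.argsort(-row[nbrs], kind="stable")]
        kept = order[:K]
        S[i, kept] = row[kept] / (2.0 * row[kept].sum())
    return S


def network_distance(Wa: np.ndarray, Wb: np.ndarray) -> float:
    """Frobenius (entrywise Euclidean) distance between aligned matrices."""
    Wa = np.asarray(Wa, dtype=float)
    Wb = np.asarray(Wb, dtype=float)
    if Wa.shape != Wb.shape:
        raise ValueError(f"shape mismatch: {Wa.shape} vs {Wb.shape}")
    return float(np.linalg.norm(Wa - Wb))


def diffuse_pair(
    Pa: np.ndarray,
    Pb: np.ndarray,
    Sa: np.ndarray,
    Sb: np.ndarray,
    t_max: int = 20,
    renormalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-diffuse two full kernels through each other's KNN kernels.

    Runs exactly ``t_max`` simultaneous (Jacobi-style) updates

        Pa <- Sa @ Pb @ Sa.T      Pb <- Sb @ Pa @ Sb.T

    where both right-hand sides use the previous iteration's matrices. No
    per-iteration renormalization is applied by default; ``renormalize=True``
    restores row-stochasticity after each step for sensitivity analysis.
    """
    Pa_t, Pb_t = np.asarray(Pa, float), np.asarray(Pb, float)
    for _ in range(t_max):
        Pa_next = Sa @ Pb_t @ Sa.T
        Pb_next = Sb @ Pa_t @ Sb.T
        if renormalize:
            Pa_next = _row_renorm(Pa_next)
            Pb_next = _row_renorm(Pb_next)
        Pa_t, Pb_t = Pa_next, Pb_next
    return Pa_t, Pb_t


def _row_renorm(P: np.ndarray) -> np.ndarray:
    sums = P.sum(axis=1)
    safe = np.where(sums == 0.0, 1.0, sums)
    return P / safe[:, None]


def fuse_pair(Pa_t: np.ndarray, Pb_t: np.ndarray) -> np.ndarray:
    """Average the two diffused status matrices into one fused matrix."""
    if Pa_t.shape != Pb_t.shape:
        raise ValueError(f"shape mismatch: {Pa_t.shape} vs {Pb_t.shape}")
    return (Pa_t + Pb_t) / 2.0


def fuse_all(
    networks: Sequence[ActiveNetwork],
    K: int = 20,
    t_max: int = 20,
    renormalize: bool = False,
) -> FusedNetwork:
    """Hierarchically fuse all active networks into a single matrix.

    The first merge joins the two networks closest in Frobenius distance of
    their W matrices (ties broken by lowest time-index pair); the fused R then
    plays the role of a weight matrix, its kernels are rebuilt, and R absorbs
    the nearest remaining network until one matrix remains. Networks with no
    edges at all are skipped (logged): an all-zero W is at distance zero from
    every other all-zero W and carries nothing to fuse.

    With a single usable network the result is simply its full kernel.
    """
    usable = [net for net in networks if net.W.any()]
    skipped = len(networks) - len(usable)
    if skipped:
        logger.info("skipping %d empty active network(s)", skipped)
    if not usable:
        raise ValueError("all active networks are empty; nothing to fuse")
    node_ids = usable[0].node_ids
    for net in usable[1:]:
        if net.node_ids != node_ids:
            raise ValueError("active networks are not union-aligned")

    if len(usable) == 1:
        return FusedNetwork(node_ids, full_kernel(usable[0].W), ())

    # entries: (label, W); labels "t<i>" for inputs, "R<j>" for merge results
    entries = [(f"t{net.time_index}", net.W, net.time_index) for net in usable]
    order: list[tuple[str, str]] = []

    # first merge: globally closest pair, tie-break on lowest (ti, tj)
    best = None
    for ai in range(len(entries)):
        for bi in range(ai + 1, len(entries)):
            d = network_distance(entries[ai][1], entries[bi][1])
            lo, hi = sorted((entries[ai][2], entries[bi][2]))
            key = (d, lo, hi)
            if best is None or key < best[0]:
                best = (key, ai, bi)
    _, ai, bi = best
    # canonical pair order: lower time index first, whatever the list order
    if entries[ai][2] > entries[bi][2]:
        ai, bi = bi, ai
    label_a, Wa, _ = entries[ai]
    label_b, Wb, _ = entries[bi]
    R = _fuse_two(Wa, Wb, K, t_max, renormalize)
    order.append((label_a, label_b))
    remaining = [e for idx, e in enumerate(entries) if idx not in (ai, bi)]
    merge_count = 1

    while remaining:
        dists = [
            (network_distance(R, Wk), tk, idx)
            for idx, (_, Wk, tk) in enumerate(remaining)
        ]
        _, _, idx = min(dists)
        label_k, Wk, _ = remaining.pop(idx)
        R = _fuse_two(R, Wk, K, t_max, renormalize)
        order.append((f"R{merge_count}", label_k))
        merge_count += 1

    return FusedNetwork(node_ids, R, tuple(order))


def _fuse_two(
    Wa: np.ndarray, Wb: np.ndarray, K: int, t_max: int, renormalize: bool
) -> np.ndarray:
    Pa, Pb = full_kernel(Wa), full_kernel(Wb)
    Sa, Sb = knn_kernel(Wa, K), knn_kernel(Wb, K)
    Pa_t, Pb_t = diffuse_pair(Pa, Pb, Sa, Sb, t_max, renormalize)
    return fuse_pair(Pa_t, Pb_t)
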