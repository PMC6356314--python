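"""Rank genes in the fused network: orthology random walk + local entropy.

The global score ``pr`` is the fixed point of a restart walk on the
row-normalized fused matrix H, seeded by orthology: genes conserved across
many reference species restart the walk with higher preference. The local
score is the interaction-frequency entropy (IFE) of a gene's K strongest
fused-network neighbors, min-max scaled. The final score blends the two,
FDP = lam*pr + (1-lam)*IFE.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "row_normalize",
    "orthology_restart",
    "random_walk",
    "interaction_frequency_entropy",
    "minmax_normalize",
    "fdp_score",
    "rank_fused_network",
]


def row_normalize(R: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; all-zero rows become unit diagonal rows."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or not np.all(np.isfinite(R)):
        raise ValueError("fused matrix must be non-negative and finite")
    sums = R.sum(axis=1)
    zero = sums == 0.0
    safe = np.where(zero, 1.0, sums)
    H = R / safe[:, None]
    if zero.any():
        H[zero, :] = 0.0
        H[zero, np.flatnonzero(zero)] = 1.0
    return H


def orthology_restart(
    counts: Mapping[str, int], node_ids: Sequence[str]
) -> np.ndarray:
    """Restart preference d: ortholog counts normalized by the network max.

    Genes absent from ``counts`` get count 0 and stay rankable through
    topology alone. d is normalized by the maximum, not the sum — it is a
    preference vector, not a probability distribution.
    """
    o = np.array([float(counts.get(g, 0)) for g in node_ids])
    if np.any(o < 0):
        raise ValueError("ortholog counts must be non-negative")
    m = o.max() if o.size else 0.0
    return o / m if m > 0 else o


def random_walk(
    H: np.ndarray,
    d: np.ndarray,
    a: float = 0.5,
    eps: float = 1e-10,
    max_iter: int = 10000,
    transpose: bool = False,
) -> np.ndarray:
    """Iterate pr = (1-a)*d + a*H@pr from pr0 = d to its fixed point.

    Each gene pulls score from its fused-network neighbors (H@pr with H
    row-normalized); ``transpose=True`` pushes instead (H.T@pr), exposed for
    sensitivity analysis. Converges geometrically with ratio <= a for a < 1.
    """
    if not 0.0 <= a < 1.0:
        raise ValueError(f"restart parameter a must be in [0, 1), got {a}")
    M = H.T if transpose else H
    pr = d.astype(float).copy()
    for _ in range(max_iter):
        nxt = (1.0 - a) * d + a * (M @ pr)
        if np.abs(nxt - pr).sum() <= eps:
            return nxt
        pr = nxt
    raise RuntimeError(f"random walk did not converge in {max_iter} iterations")


def interaction_frequency_entropy(H: np.ndarray, K: int = 20) -> np.ndarray:
    """Raw IFE per gene over its K strongest neighbors.

    For gene i let KNN(i) be its (up to) K neighbors of largest h(i, .),
    excluding itself, ties keeping lexicographically smallest ids (rows are
    aligned to sorted ids, so stable index order suffices). Then

        IFE(i) = -sum_k q log q,   q = h(i, k) / |KNN(i)|

    with natural log, exactly as the entries stand — the q need not sum to 1.
    Genes with no neighbors get IFE 0.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    ife = np.zeros(n)
    for i in range(n):
        row = H[i].copy()
        row[i] = 0.0
        nbrs = np.flatnonzero(row > 0.0)
        if nbrs.size == 0:
            continue
        order = nbrs[np.argsort(-row[nbrs], kind="stable")]
        kept = order[:K]
        q = row[kept] / kept.size
        ife[i] = float(-(q * np.log(q)).sum())
    return ife


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant vector maps to all zeros."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def fdp_score(
    node_ids: Sequence[str],
    pr: np.ndarray,
    ife_normalized: np.ndarray,
    lam: float = 0.8,
) -> pd.DataFrame:
    """Blend the global and local scores and rank genes.

    Returns a DataFrame with columns (rank, gene, pr, ife, fdp) sorted by
    descending fdp; ties broken by larger pr, then lexicographic gene id.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    if not (len(node_ids) == len(pr) == len(ife_normalized)):
        raise ValueError("score vectors and node ids differ in length")
    df = pd.DataFrame(
        {
            "gene": list(node_ids),
            "pr": np.asarray(pr, float),
            "ife": np.asarray(ife_normalized, float),
        }
    )
    df["fdp"] = lam * df["pr"] + (1.0 - lam) * df["ife"]
    df = df.sort_values(
        ["fdp", "pr", "gene"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def rank_fused_network(
    R: np.ndarray,
    node_ids: Sequence[str],
    ortholog_counts: Mapping[str, int],
    a: float = 0.5,
    lam: float = 0.8,
    K: int = 20,
    eps: float = 1e-10,
    transpose_walk: bool = False,
) -> pd.DataFrame:
    """Full ranking stage: row-normalize, walk, entropy, blend."""
    H = row_normalize(R)
    d = orthology_restart(ortholog_counts, node_ids)
    pr = random_walk(H, d, a=a, eps=eps, transpose=transpose_walk)
    ife = minmax_normalize(interaction_frequency_entropy(H, K))
    return fdp_score(node_ids, pr, ife, lam)
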