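"""Score a gene ranking against a known-essential list.

Three standard views: top-T hit counts (how many true essentials among the T
highest-ranked genes), the jackknife curve (cumulative essentials as the
cutoff grows), and the precision-recall curve over every cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EvaluationReport",
    "top_t_accuracy",
    "jackknife_curve",
    "precision_recall_curve",
    "evaluate_ranking",
]


@dataclass(frozen=True)
class EvaluationReport:
    top_counts: dict[int, int]
    top_fractions: dict[int, float]
    jackknife: list[tuple[int, int]]
    pr_curve: list[tuple[float, float]]  # (recall, precision) per cutoff
    n_ranked: int
    n_essentials: int

    def to_dict(self) -> dict:
        return {
            "top_counts": {str(t): c for t, c in self.top_counts.items()},
            "top_fractions": {str(t): f for t, f in self.top_fractions.items()},
            "jackknife": [list(p) for p in self.jackknife],
            "pr_curve": [list(p) for p in self.pr_curve],
            "n_ranked": self.n_ranked,
            "n_essentials": self.n_essentials,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _hit_vector(ranking: Sequence[str], essentials: set[str]) -> np.ndarray:
    return np.array([g in essentials for g in ranking], dtype=bool)


def top_t_accuracy(
    ranking: Sequence[str], essentials: Iterable[str], T: int
) -> tuple[int, float]:
    """Count and fraction of true essentials among the top-T ranked genes."""
    essentials = set(essentials)
    if not essentials:
        raise ValueError("essential gene set is empty")
    if T > len(ranking):
        raise ValueError(f"T={T} exceeds ranking length {len(ranking)}")
    count = int(_hit_vector(ranking[:T], essentials).sum())
    return count, count / T


def jackknife_curve(
    ranking: Sequence[str], essentials: Iterable[str]
) -> list[tuple[int, int]]:
    """Cumulative essentials among the top-n genes for n = 1 .. F."""
    if not ranking:
        raise ValueError("ranking is empty")
    hits = _hit_vector(ranking, set(essentials))
    cum = np.cumsum(hits)
    return [(n, int(c)) for n, c in enumerate(cum, start=1)]


def precision_recall_curve(
    ranking: Sequence[str],
    essentials: Iterable[str],
    restrict_to_ranked: bool = True,
) -> list[tuple[float, float]]:
    """(recall, precision) at every cutoff n = 1 .. F.

    By default the recall denominator counts only essentials present in the
    ranking (the fused network's gene universe); ``restrict_to_ranked=False``
    uses the full essential list instead.
    """
    if not ranking:
        raise ValueError("ranking is empty")
    essentials = set(essentials)
    hits = _hit_vector(ranking, essentials)
    denom = int(hits.sum()) if restrict_to_ranked else len(essentials)
    cum = np.cumsum(hits)
    ns = np.arange(1, len(ranking) + 1)
    precision = cum / ns
    recall = cum / denom if denom > 0 else np.zeros_like(precision)
    return list(zip(recall.tolist(), precision.tolist()))


def evaluate_ranking(
    ranking: Sequence[str],
    essentials: Iterable[str],
    T_list: Sequence[int] = (100, 200, 300, 400),
    restrict_to_ranked: bool = True,
) -> EvaluationReport:
    """Full report: top-T counts, jackknife curve, PR curve."""
    essentials = set(essentials)
    usable_T = [T for T in T_list if T <= len(ranking)]
    counts, fracs = {}, {}
    for T in usable_T:
        c, f = top_t_accuracy(ranking, essentials, T)
        counts[T], fracs[T] = c, f
    return EvaluationReport(
        top_counts=counts,
        top_fractions=fracs,
        jackknife=jackknife_curve(ranking, essentials),
        pr_curve=precision_recall_curve(ranking, essentials, restrict_to_ranked),
        n_ranked=len(ranking),
        n_essentials=len(set(ranking) & essentials)
        if restrict_to_ranked
        else len(essentials),
    )
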