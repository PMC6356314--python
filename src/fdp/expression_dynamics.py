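"""Classify expression profiles and extract per-time-point active networks.

A time-course expression profile is either *time-dependent* (its values carry
autocorrelation structure detectable by an autoregressive model of some order
p >= 1), *time-independent* (an order-0, intercept-only model fits as well), or
*noise* (time-independent with a very low mean level). Noise genes are dropped;
the remaining genes are *active* at a time point when their expression exceeds
a per-gene k-sigma threshold, and the active networks are the subgraphs of the
static PPI induced on each time point's active gene set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "DynamicsClass",
    "DynamicsLabel",
    "ActivityThreshold",
    "ar_order_pvalue",
    "classify_profile",
    "classify_profiles",
    "activity_threshold",
    "active_genes_at",
    "build_active_networks",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """One gene's expression series at M equally spaced time points.

    ``sd_sigma`` uses the population formula (divide by M) by default, because
    the damping factor F = 1/(1 + sigma^2) of the activity threshold is a
    smoothing heuristic rather than an inferential quantity; pass
    ``population_sd=False`` at construction for the sample formula.
    """

    gene_id: str
    values: np.ndarray
    population_sd: bool = True
    mean_u: float = field(init=False)
    sd_sigma: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"{self.gene_id}: expression series must be 1-D")
        if values.size < 5:
            raise ValueError(
                f"{self.gene_id}: need at least 5 time points for an AR order "
                f"test, got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{self.gene_id}: non-finite expression values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mean_u", float(values.mean()))
        ddof = 0 if self.population_sd else 1
        object.__setattr__(self, "sd_sigma", float(values.std(ddof=ddof)))

    @property
    def n_timepoints(self) -> int:
        return int(self.values.size)

    @property
    def max_order(self) -> int:
        """Largest admissible AR order, floor((M - 1) / 2)."""
        return (self.n_timepoints - 1) // 2


class DynamicsLabel(str, Enum):
    TIME_DEPENDENT = "TIME_DEPENDENT"
    TIME_INDEPENDENT = "TIME_INDEPENDENT"
    NOISE = "NOISE"


@dataclass(frozen=True)
class DynamicsClass:
    """Classification outcome plus the smallest AR-order p-value observed."""

    label: DynamicsLabel
    min_pvalue: float | None = None


@dataclass(frozen=True)
class ActivityThreshold:
    """Per-gene activity cutoff u + k*sigma*(1 - F) with F = 1/(1 + sigma^2)."""

    gene_id: str
    threshold: float
    k: float
    F: float


def ar_order_pvalue(profile: ExpressionProfile, order: int) -> float:
    """p-value of AR(order) explaining the series better than order 0.

    Fits x_m = b0 + b1*x_{m-1} + ... + bp*x_{m-p} by ordinary least squares on
    the lag-embedded rows m = p+1 .. M, and compares it with the intercept-only
    model on the same rows via the nested-model F statistic on
    (p, M - 2p - 1) degrees of freedom.

    A response with zero variance after lag embedding returns 1.0: the
    intercept-only model is already exact.
    """
    x = profile.values
    M = x.size
    p = int(order)
    if not 1 <= p <= (M - 1) // 2:
        raise ValueError(
            f"AR order must satisfy 1 <= order <= (M-1)/2 = {(M - 1) // 2}, "
            f"got {order}"
        )
    y = x[p:]
    n = y.size
    rss0 = float(np.sum((y - y.mean()) ** 2))
    # relative zero-variance guard: a constant series stored in floats has
    # residuals at rounding scale, not exactly zero
    tiny = n * (100.0 * np.finfo(float).eps * (1.0 + abs(float(y.mean())))) ** 2
    if rss0 <= tiny:
        return 1.0
    # lag-embedded design: column j holds x shifted by lag j+1
    X = np.empty((n, p + 1))
    X[:, 0] = 1.0
    for lag in range(1, p + 1):
        X[:, lag] = x[p - lag : M - lag]
    _, res, rank, _ = np.linalg.lstsq(X, y)
    if rank < X.shape[1] or res.size == 0:
        fitted = X @ np.linalg.lstsq(X, y)[0]
        rss1 = float(np.sum((y - fitted) ** 2))
    else:
        rss1 = float(res[0])
    df2 = n - (p + 1)
    if df2 <= 0:
        return 1.0
    rss1 = max(rss1, 0.0)
    if rss1 <= rss0 * 1e-15:
        return 0.0
    f_stat = ((rss0 - rss1) / p) / (rss1 / df2)
    if f_stat <= 0.0:
        return 1.0
    return float(stats.f.sf(f_stat, p, df2))


def classify_profile(
    profile: ExpressionProfile,
    p_threshold: float = 0.01,
    noise_mean_cutoff: float = 0.5,
) -> DynamicsClass:
    """Label a profile TIME_DEPENDENT, TIME_INDEPENDENT, or NOISE.

    The gene is time-dependent if the minimum p-value over all admissible AR
    orders 1 <= p <= (M-1)/2 falls below ``p_threshold`` — deliberately with
    no multiplicity correction, since a single sufficiently good order
    suffices. A time-independent gene whose mean expression is below
    ``noise_mean_cutoff`` is demoted to NOISE.
    """
    pvals = [ar_order_pvalue(profile, p) for p in range(1, profile.max_order + 1)]
    min_p = min(pvals)
    if min_p < p_threshold:
        return DynamicsClass(DynamicsLabel.TIME_DEPENDENT, min_p)
    if profile.mean_u < noise_mean_cutoff:
        return DynamicsClass(DynamicsLabel.NOISE, min_p)
    return DynamicsClass(DynamicsLabel.TIME_INDEPENDENT, min_p)


def classify_profiles(
    profiles: Iterable[ExpressionProfile],
    p_threshold: float = 0.01,
    noise_mean_cutoff: float = 0.5,
) -> dict[str, DynamicsClass]:
    return {
        prof.gene_id: classify_profile(prof, p_threshold, noise_mean_cutoff)
        for prof in profiles
    }


def activity_threshold(profile: ExpressionProfile, k: float = 2.5) -> ActivityThreshold:
    """k-sigma activity threshold u + k*sigma*(1 - F), F = 1/(1 + sigma^2).

    The damping factor F shrinks the sigma correction for low-variance genes,
    so that genes whose expression barely moves are not forever inactive by a
    threshold far above anything they reach.
    """
    sigma = profile.sd_sigma
    F = 1.0 / (1.0 + sigma**2)
    return ActivityThreshold(
        gene_id=profile.gene_id,
        threshold=profile.mean_u + k * sigma * (1.0 - F),
        k=k,
        F=F,
    )


def active_genes_at(
    profiles: Mapping[str, ExpressionProfile],
    classes: Mapping[str, DynamicsClass],
    t: int,
    k: float = 2.5,
) -> set[str]:
    """Genes whose expression strictly exceeds their threshold at time t.

    ``t`` is 1-based (1 .. M). NOISE genes never qualify; the comparison is
    strict, so a zero-variance gene (threshold equal to its constant value)
    is never active.
    """
    active: set[str] = set()
    for gene, prof in profiles.items():
        cls = classes.get(gene)
        if cls is None:
            logger.warning("gene %s has no classification; excluded", gene)
            continue
        if cls.label is DynamicsLabel.NOISE:
            continue
        if not 1 <= t <= prof.n_timepoints:
            raise ValueError(f"time index {t} outside 1..{prof.n_timepoints}")
        if prof.values[t - 1] > activity_threshold(prof, k).threshold:
            active.add(gene)
    return active


def build_active_networks(
    net: nx.Graph,
    profiles: Mapping[str, ExpressionProfile],
    classes: Mapping[str, DynamicsClass],
    k: float = 2.5,
) -> list[nx.Graph]:
    """Induce the static PPI on each time point's active gene set.

    Returns M graphs in time order; empty graphs are permitted for individual
    time points, but if every time point is empty the expression data carry no
    dynamic signal and a ``ValueError`` is raised. PPI nodes without an
    expression profile are never active.
    """
    if not profiles:
        raise ValueError("no expression profiles supplied")
    M = next(iter(profiles.values())).n_timepoints
    lengths = {p.n_timepoints for p in profiles.values()}
    if lengths != {M}:
        raise ValueError(f"profiles disagree on series length: {sorted(lengths)}")

    # thresholds are recomputed inside active_genes_at; precompute activity as
    # a vectorized pass instead to keep M=36 sweeps cheap
    networks: list[nx.Graph] = []
    thresholds = {
        g: activity_threshold(p, k).threshold
        for g, p in profiles.items()
        if classes.get(g) is not None
        and classes[g].label is not DynamicsLabel.NOISE
    }
    node_set = set(net.nodes)
    for t in range(1, M + 1):
        active = {
            g
            for g, thr in thresholds.items()
            if g in node_set and profiles[g].values[t - 1] > thr
        }
        networks.append(net.subgraph(active).copy())
    if all(g.number_of_nodes() == 0 for g in networks):
        raise ValueError("no dynamic signal: zero active genes at every time point")
    return networks
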