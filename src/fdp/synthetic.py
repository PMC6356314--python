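"""Synthetic fixtures: PPI, time-course expression, orthology, essentials.

The generator plants the statistical structure the method assumes. Essential
genes are early (hub) nodes of a preferential-attachment graph, expressed as
high-mean, low-noise sinusoids whose peaks clear their own k-sigma activity
threshold, and carry high ortholog counts. Non-essential genes split into
lower-mean periodic genes, irregular (time-independent, high-variance) genes,
and flat low-mean noise genes included deliberately to exercise the noise
filter. Everything is reproducible from the seed, and the ground truth
(labels, planted dynamics classes, per-time-point active sets) is emitted
alongside the data.

A sinusoid of amplitude A has sd ~ A/sqrt(2), so its peak clears its own
threshold u + 2.5*sigma*(1-F) only when A is below roughly 1.6; the default
amplitude 1.0 leaves each periodic gene active around its peak phases.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from fdp.expression_dynamics import (
    DynamicsLabel,
    ExpressionProfile,
    activity_threshold,
    classify_profile,
)

__all__ = ["FixtureSpec", "Fixture", "generate"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_genes: int = 300
    n_timepoints: int = 36
    fraction_essential: float = 0.15
    seed: int = 0
    ba_edges: int = 3  # preferential-attachment edges per new node
    # periodic profiles (essential and periodic non-essential genes)
    period: float = 12.0
    amplitude: float = 1.0
    essential_mean: tuple[float, float] = (2.5, 3.5)
    essential_noise_sd: float = 0.1
    periodic_mean: tuple[float, float] = (1.0, 2.0)
    periodic_noise_sd: float = 0.2
    # irregular (time-independent) non-essential genes
    irregular_mean: tuple[float, float] = (0.8, 2.0)
    irregular_sd: float = 1.0
    # flat noise genes (mean below the 0.5 noise cutoff)
    flat_mean: tuple[float, float] = (0.05, 0.4)
    flat_sd: float = 0.05
    # composition of the non-essential pool
    frac_periodic: float = 0.5
    frac_irregular: float = 0.3
    # orthology: counts ~ Binomial(n_species, p), p per gene
    n_species: int = 99
    essential_ortholog_p: tuple[float, float] = (0.25, 0.75)
    nonessential_ortholog_p: tuple[float, float] = (0.0, 0.25)
    # activity threshold used when recording ground-truth active sets
    k: float = 2.5

    def __post_init__(self) -> None:
        if self.n_genes < 20:
            raise ValueError("need at least 20 genes")
        if not 0.0 < self.fraction_essential < 0.5:
            raise ValueError("fraction_essential must be in (0, 0.5)")
        if self.n_timepoints < 5:
            raise ValueError("need at least 5 time points")
        if self.ba_edges >= self.n_genes:
            raise ValueError("more attachment edges than available nodes")


@dataclass
class Fixture:
    """One generated dataset plus its ground truth."""

    spec: FixtureSpec
    network: nx.Graph
    expression: pd.DataFrame  # genes x time points
    ortholog_counts: dict[str, int]
    essentials: set[str]
    planted_class: dict[str, str]  # gene -> planted dynamics label
    active_truth: list[set[str]] = field(repr=False)  # per time point

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the four input files plus a truth sidecar; returns paths."""
        from fdp import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ppi": outdir / "ppi.tsv",
            "expression": outdir / "expression.tsv",
            "orthology": outdir / "orthology.tsv",
            "essentials": outdir / "essentials.txt",
            "truth": outdir / "truth.json",
        }
        io.write_edge_list(self.network, paths["ppi"])
        io.write_expression(self.expression, paths["expression"])
        io.write_orthology(self.ortholog_counts, paths["orthology"])
        paths["essentials"].write_text(
            "".join(f"{g}\n" for g in sorted(self.essentials))
        )
        truth = {
            "spec": dataclasses.asdict(self.spec),
            "essentials": sorted(self.essentials),
            "planted_class": self.planted_class,
            "active_truth": [sorted(s) for s in self.active_truth],
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


def _gene_id(i: int) -> str:
    return f"g{i:05d}"


def _sinusoid(
    rng: np.random.Generator,
    M: int,
    mean: float,
    amplitude: float,
    period: float,
    noise_sd: float,
) -> np.ndarray:
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(1, M + 1, dtype=float)
    x = mean + amplitude * np.sin(2.0 * np.pi * t / period + phase)
    return np.clip(x + rng.normal(0.0, noise_sd, M), 0.0, None)


def _draw_until(draw, predicate, max_tries: int = 200) -> np.ndarray:
    """Redraw a profile until the planted class holds, so truth is exact."""
    for _ in range(max_tries):
        x = draw()
        if predicate(x):
            return x
    raise RuntimeError("could not realize the planted profile class")


def generate(spec: FixtureSpec) -> Fixture:
    """Generate one fixture dataset deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    M = spec.n_timepoints
    genes = [_gene_id(i) for i in range(n)]
    n_ess = int(n * spec.fraction_essential)

    graph = nx.barabasi_albert_graph(n, spec.ba_edges, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {i: genes[i] for i in range(n)})
    # early preferential-attachment nodes are the hubs; plant essentials there
    essentials = set(genes[:n_ess])

    non_ess = genes[n_ess:]
    n_periodic = int(len(non_ess) * spec.frac_periodic)
    n_irregular = int(len(non_ess) * spec.frac_irregular)
    periodic_ne = non_ess[:n_periodic]
    irregular_ne = non_ess[n_periodic : n_periodic + n_irregular]
    flat_ne = non_ess[n_periodic + n_irregular :]

    def classifies_as(x: np.ndarray, label: DynamicsLabel) -> bool:
        prof = ExpressionProfile("tmp", x)
        return classify_profile(prof).label is label

    expr = {}
    planted: dict[str, str] = {}
    for g in sorted(essentials):
        mean = rng.uniform(*spec.essential_mean)
        expr[g] = _sinusoid(
            rng, M, mean, spec.amplitude, spec.period, spec.essential_noise_sd
        )
        planted[g] = "periodic"
    for g in periodic_ne:
        mean = rng.uniform(*spec.periodic_mean)
        expr[g] = _sinusoid(
            rng, M, mean, spec.amplitude, spec.period, spec.periodic_noise_sd
        )
        planted[g] = "periodic"
    for g in irregular_ne:
        mean = rng.uniform(*spec.irregular_mean)
        # redraw the rare draws that mimic autocorrelation, so the planted
        # time-independent class is exact rather than merely likely
        expr[g] = _draw_until(
            lambda: np.clip(rng.normal(mean, spec.irregular_sd, M), 0.0, None),
            lambda x: classifies_as(x, DynamicsLabel.TIME_INDEPENDENT),
        )
        planted[g] = "irregular"
    for g in flat_ne:
        mean = rng.uniform(*spec.flat_mean)
        expr[g] = _draw_until(
            lambda: np.clip(rng.normal(mean, spec.flat_sd, M), 0.0, None),
            lambda x: classifies_as(x, DynamicsLabel.NOISE),
        )
        planted[g] = "flat"

    expression = pd.DataFrame.from_dict(expr, orient="index").sort_index()
    expression.columns = [f"t{j}" for j in range(1, M + 1)]
    expression.index.name = "gene"

    counts: dict[str, int] = {}
    for g in genes:
        lo, hi = (
            spec.essential_ortholog_p
            if g in essentials
            else spec.nonessential_ortholog_p
        )
        counts[g] = int(rng.binomial(spec.n_species, rng.uniform(lo, hi)))

    active_truth = _active_truth(expression, planted, spec.k)
    return Fixture(
        spec=spec,
        network=graph,
        expression=expression,
        ortholog_counts=counts,
        essentials=essentials,
        planted_class=planted,
        active_truth=active_truth,
    )


def _active_truth(
    expression: pd.DataFrame, planted: dict[str, str], k: float
) -> list[set[str]]:
    """Active sets implied by the planted classes and the k-sigma rule."""
    M = expression.shape[1]
    sets: list[set[str]] = [set() for _ in range(M)]
    for g, row in expression.iterrows():
        if planted[g] == "flat":
            continue
        prof = ExpressionProfile(str(g), row.to_numpy())
        thr = activity_threshold(prof, k).threshold
        for t in np.flatnonzero(prof.values > thr):
            sets[int(t)].add(str(g))
    return sets
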