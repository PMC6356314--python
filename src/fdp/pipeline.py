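"""End-to-end pipeline: dynamics -> fusion -> ranking -> evaluation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from fdp import io
from fdp.config import PipelineConfig
from fdp.evaluation import EvaluationReport, evaluate_ranking
from fdp.expression_dynamics import (
    DynamicsClass,
    ExpressionProfile,
    build_active_networks,
    classify_profiles,
)
from fdp.network_fusion import FusedNetwork, align_active_networks, fuse_all
from fdp.ranking import rank_fused_network

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_files"]


@dataclass
class PipelineResult:
    classes: dict[str, DynamicsClass]
    active_networks: list[nx.Graph]
    fused: FusedNetwork
    ranking: pd.DataFrame
    report: EvaluationReport | None


def run_pipeline(
    network: nx.Graph,
    profiles: Mapping[str, ExpressionProfile],
    ortholog_counts: Mapping[str, int],
    essentials: set[str] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    Evaluation runs only when an essential-gene list is supplied; the ranking
    itself never sees the labels.
    """
    cfg = config or PipelineConfig()

    logger.info("stage 1/4: classifying %d expression profiles", len(profiles))
    try:
        classes = classify_profiles(
            profiles.values(), cfg.p_threshold, cfg.noise_mean
        )
        active = build_active_networks(network, profiles, classes, cfg.k)
    except Exception as exc:
        raise RuntimeError(f"expression-dynamics stage failed: {exc}") from exc

    logger.info("stage 2/4: fusing %d active networks", len(active))
    try:
        aligned = align_active_networks(active, cfg.mu)
        fused = fuse_all(
            aligned, K=cfg.K, t_max=cfg.diffusion_iters,
            renormalize=cfg.renormalize_diffusion,
        )
    except Exception as exc:
        raise RuntimeError(f"network-fusion stage failed: {exc}") from exc

    logger.info("stage 3/4: ranking %d fused-network genes", len(fused.node_ids))
    try:
        ranking = rank_fused_network(
            fused.R,
            fused.node_ids,
            ortholog_counts,
            a=cfg.a,
            lam=cfg.lam,
            K=cfg.K,
            eps=cfg.eps,
            transpose_walk=cfg.transpose_walk,
        )
    except Exception as exc:
        raise RuntimeError(f"ranking stage failed: {exc}") from exc

    report = None
    if essentials is not None:
        logger.info("stage 4/4: evaluating against %d essentials", len(essentials))
        try:
            report = evaluate_ranking(
                ranking["gene"].tolist(), essentials, cfg.T_list
            )
        except Exception as exc:
            raise RuntimeError(f"evaluation stage failed: {exc}") from exc

    return PipelineResult(classes, active, fused, ranking, report)


def run_pipeline_files(
    ppi_path: str | Path,
    expression_path: str | Path,
    orthology_path: str | Path,
    essentials_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """File-based front end: read inputs, run, optionally persist artifacts."""
    network = io.read_edge_list(ppi_path)
    profiles = io.read_expression(expression_path)
    try:
        counts = io.read_orthology(orthology_path)
    except FileNotFoundError as exc:
        raise RuntimeError(
            f"ranking stage requires the orthology file {orthology_path}: {exc}"
        ) from exc
    essentials = io.read_essentials(essentials_path) if essentials_path else None

    result = run_pipeline(network, profiles, counts, essentials, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_ranking(result.ranking, outdir / "ranking.tsv")
        if result.report is not None:
            result.report.to_json(outdir / "report.json")
        if keep_intermediates:
            _write_intermediates(result, outdir)
    return result


def _write_intermediates(result: PipelineResult, outdir: Path) -> None:
    with (outdir / "classification.tsv").open("w") as fh:
        fh.write("gene\tclass\tmin_pvalue\n")
        for g in sorted(result.classes):
            cls = result.classes[g]
            pv = "" if cls.min_pvalue is None else f"{cls.min_pvalue:.6g}"
            fh.write(f"{g}\t{cls.label.value}\t{pv}\n")
    active_dir = outdir / "active_networks"
    active_dir.mkdir(exist_ok=True)
    for t, g in enumerate(result.active_networks, start=1):
        io.write_edge_list(g, active_dir / f"active_t{t:02d}.tsv")
    io.write_fused_matrix(
        result.fused.node_ids,
        result.fused.R,
        outdir / "fused_dense.tsv",
        outdir / "fused_triplets.tsv",
    )
    io.write_merge_trace(result.fused.fusion_order, outdir / "merge_trace.txt")
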