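"""Readers and writers for every file format the pipeline touches.

All formats are plain text: TSV edge lists, a genes-by-time-points expression
table, a two-column orthology table, one-ID-per-line essential lists, labeled
dense / sparse-triplet matrix dumps, and a parenthesized merge trace.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from fdp.expression_dynamics import ExpressionProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "write_expression",
    "read_orthology",
    "write_orthology",
    "read_essentials",
    "write_weighted_edge_list",
    "write_fused_matrix",
    "read_fused_matrix",
    "write_merge_trace",
    "write_ranking",
    "read_ranking",
]


def read_edge_list(path: str | Path, header: bool = False) -> nx.Graph:
    """Read an undirected two-column edge list.

    Self-loops and duplicate pairs (including reversed duplicates) are
    dropped, with counts logged.
    """
    path = Path(path)
    graph = nx.Graph()
    loops = dups = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated ids")
            u, v = fields[0], fields[1]
            if u == v:
                loops += 1
                continue
            if graph.has_edge(u, v):
                dups += 1
                continue
            graph.add_edge(u, v)
    if loops or dups:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)", path, loops, dups
        )
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_expression(path: str | Path) -> dict[str, ExpressionProfile]:
    """Read a `gene<TAB>t1..tM` table into expression profiles.

    Missing or non-numeric values are rejected: the activity model assumes a
    complete series per gene.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"{path}: missing expression values (e.g. genes {bad})")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return {
        str(g): ExpressionProfile(str(g), row.to_numpy(dtype=float))
        for g, row in df.iterrows()
    }


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", float_format="%.6f")


def read_orthology(path: str | Path) -> dict[str, int]:
    """Read `gene<TAB>count` ortholog counts."""
    counts: dict[str, int] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>count")
            try:
                c = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: count is not an integer") from exc
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative ortholog count")
            counts[fields[0]] = c
    return counts


def write_orthology(counts: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(counts):
            fh.write(f"{g}\t{counts[g]}\n")


def read_essentials(path: str | Path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def write_weighted_edge_list(
    node_ids: Sequence[str], W: np.ndarray, path: str | Path
) -> None:
    """Write the upper triangle of a symmetric weight matrix as node-node-w."""
    with Path(path).open("w") as fh:
        rows, cols = np.nonzero(np.triu(W, k=1))
        for i, j in zip(rows.tolist(), cols.tolist()):
            fh.write(f"{node_ids[i]}\t{node_ids[j]}\t{W[i, j]:.10g}\n")


def write_fused_matrix(
    node_ids: Sequence[str], R: np.ndarray, dense_path: str | Path,
    triplet_path: str | Path | None = None,
) -> None:
    """Write a labeled dense TSV and optionally a sparse triplet TSV."""
    df = pd.DataFrame(R, index=list(node_ids), columns=list(node_ids))
    df.index.name = "gene"
    df.to_csv(dense_path, sep="\t", float_format="%.17g")
    if triplet_path is not None:
        with Path(triplet_path).open("w") as fh:
            for i, j in zip(*np.nonzero(R)):
                fh.write(f"{node_ids[i]}\t{node_ids[j]}\t{R[i, j]:.17g}\n")


def read_fused_matrix(dense_path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(dense_path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{dense_path}: row and column labels disagree")
    return tuple(str(g) for g in df.index), df.to_numpy(dtype=float)


def write_merge_trace(
    fusion_order: Iterable[tuple[str, str]], path: str | Path
) -> None:
    """Write the fusion order as a nested parenthesized merge trace."""
    trace = None
    lines = []
    for a, b in fusion_order:
        left = trace if a.startswith("R") and trace is not None else a
        trace = f"({left},{b})"
        lines.append(f"{a}\t{b}\n")
    with Path(path).open("w") as fh:
        fh.writelines(lines)
        if trace is not None:
            fh.write(f"{trace};\n")


def write_ranking(ranking: pd.DataFrame, path: str | Path) -> None:
    ranking.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ranking(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"rank", "gene", "pr", "ife", "fdp"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df
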