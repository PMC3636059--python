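"""Readers and writers for the exchange formats.

Everything is plain tab-separated text: expression matrices (first row
sample ids, first column gene ids), two-column condition maps, two-or-three
column target edge lists, and network tables. Networks can additionally be
exported as SIF or GraphML (via networkx). TSV output is byte-stable: edges
are sorted by (source, target).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .core import (
    EdgeConfidence,
    ExpressionDataset,
    GeneRole,
    GlobalNetwork,
    TypedEdge,
    edge_type_label,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_condition_map",
    "write_condition_map",
    "read_target_edges",
    "write_target_edges",
    "write_network",
    "read_network",
]

NETWORK_COLUMNS = ["source", "target", "edge_type", "Q", "trials", "p_value"]


def read_expression_table(path: str | Path, role: GeneRole) -> ExpressionDataset:
    """Read a genes x samples TSV matrix, tagging every gene with *role*.

    The first row holds sample ids, the first column gene ids, and the body
    must be numeric. Duplicated gene or sample ids are a validation error.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse expression table {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    frame.index.name = None
    frame.columns.name = None
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        gene, sample = bad[bad].index[0]
        raise ValueError(
            f"non-numeric expression value at gene {gene!r}, sample {sample!r} in {path}"
        )
    roles = {g: role for g in numeric.index}
    return ExpressionDataset(numeric, roles)


def write_expression_table(data: ExpressionDataset, path: str | Path) -> None:
    data.values.to_csv(path, sep="\t", index_label="gene")


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample id, condition label).

    A sample listed twice with different labels is an error; an empty file
    is an error ("no samples").
    """
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            sample, label = parts[0].strip(), parts[1].strip()
            if sample in mapping and mapping[sample] != label:
                raise ValueError(
                    f"sample {sample!r} listed with conflicting labels "
                    f"{mapping[sample]!r} and {label!r}"
                )
            mapping[sample] = label
    if not mapping:
        raise ValueError(f"no samples in condition map {path}")
    labels = sorted(set(mapping.values()))
    logger.info("condition map: %d samples, C=%d conditions %s", len(mapping), len(labels), labels)
    return mapping


def write_condition_map(conditions: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for sample in conditions:
            handle.write(f"{sample}\t{conditions[sample]}\n")


def read_target_edges(
    path: str | Path, roles: Mapping[str, GeneRole]
) -> tuple[list[TypedEdge], int]:
    """Read a 2- or 3-column target edge list (source, target[, type]).

    The type column, when absent, is inferred from the role table. Edges with
    an endpoint absent from *roles* are skipped; the skipped count is
    returned alongside the edges and logged. An edge whose stated or inferred
    type violates the five-type constraint (e.g. an mRNA source) is a
    validation error.
    """
    edges: list[TypedEdge] = []
    skipped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            source, target = parts[0], parts[1]
            if source not in roles or target not in roles:
                skipped += 1
                continue
            inferred = edge_type_label(roles[source], roles[target])
            if len(parts) == 3 and parts[2] != inferred:
                raise ValueError(
                    f"{path}:{lineno}: stated type {parts[2]!r} conflicts with "
                    f"roles ({inferred})"
                )
            edges.append(TypedEdge(source, target, inferred))
    if skipped:
        logger.warning("%s: skipped %d edges with unknown ids", path, skipped)
    return edges, skipped


def write_target_edges(edges: list[TypedEdge], path: str | Path) -> None:
    with open(path, "w") as handle:
        for e in sorted(edges):
            handle.write(f"{e.source}\t{e.target}\t{e.edge_type}\n")


def write_network(
    network: GlobalNetwork, fmt: str, path: str | Path
) -> None:
    """Write a global network as TSV, SIF, or GraphML.

    TSV columns: source, target, edge_type, Q, trials, p_value — sorted by
    (source, target) for byte stability. SIF uses the edge type as the
    relation token. GraphML carries the same attributes on edges and the
    role on nodes.
    """
    fmt = fmt.upper()
    frame = network.to_frame()
    if fmt == "TSV":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "SIF":
        with open(path, "w") as handle:
            for row in frame.itertuples(index=False):
                handle.write(f"{row.source}\t{row.edge_type}\t{row.target}\n")
    elif fmt == "GRAPHML":
        graph = nx.DiGraph()
        for node in network.nodes:
            graph.add_node(node, role=network.roles[node].name)
        for row in frame.itertuples(index=False):
            graph.add_edge(
                row.source,
                row.target,
                edge_type=row.edge_type,
                Q=int(row.Q),
                trials=int(row.trials),
                p_value=float(row.p_value),
            )
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {fmt!r} (use TSV, SIF, or GraphML)")


def read_network(
    path: str | Path,
    roles: Mapping[str, GeneRole],
    threshold: float = 0.05,
) -> GlobalNetwork:
    """Read a TSV network written by :func:`write_network` back into memory."""
    frame = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    missing = [c for c in NETWORK_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"network table {path} lacks columns {missing}")
    confidences = [
        EdgeConfidence(
            edge=TypedEdge(row.source, row.target, row.edge_type),
            Q=int(row.Q),
            trials=int(row.trials),
            p_value=float(row.p_value),
        )
        for row in frame.itertuples(index=False)
    ]
    return GlobalNetwork(roles, confidences, threshold)
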