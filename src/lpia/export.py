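"""Thresholded pathway-network export for graph viewers.

Writes the pathway-pathway network as an edge/node TSV bundle, SIF, or
GraphML, keeping only edges whose weight strictly exceeds a display
threshold (default 0.1).  Node attributes join the centrality results with
the enrichment table so a viewer can colour nodes by rich ratio and mark
latent pathways; a pathway missing from the enrichment side is exported
with the literal marker "NA", never a fabricated zero.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .core import CentralityResult, PathwayNetwork
from .errors import ConfigError, DataError

NA = "NA"

NODE_COLUMNS = ["pathway_id", "name", "rich_ratio", "enrichment_q", "latent", "centrality"]


class NetworkEdge(NamedTuple):
    """One undirected edge, emitted once with source < target."""

    source: str
    target: str
    weight: float


def edge_list(net: PathwayNetwork, threshold: float = 0.1) -> list[NetworkEdge]:
    """Edges with weight strictly greater than ``threshold``.

    Each undirected edge appears once with lexicographically ordered
    endpoints; the list is sorted by (source, target).
    """
    if threshold < 0:
        raise ConfigError(f"threshold must be >= 0, got {threshold}")
    ids = net.pathway_ids
    rows, cols = np.nonzero(np.triu(net.weights, k=1) > threshold)
    edges = [
        NetworkEdge(*sorted((ids[i], ids[j])), weight=float(net.weights[i, j]))
        for i, j in zip(rows, cols)
    ]
    return sorted(edges, key=lambda e: (e.source, e.target))


def assemble_node_attributes(
    enrich_rows: pd.DataFrame | None,
    result: CentralityResult,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Left-join centrality results with enrichment rows on pathway id.

    The node universe is the centrality side; ``latent`` is true exactly
    when the adjusted bootstrap p-value is <= alpha.  Duplicated ids on
    either side are an error.
    """
    ids = result.pathway_ids
    if len(set(ids)) != len(ids):
        raise DataError("duplicate pathway ids in centrality result")
    nodes = pd.DataFrame(
        {
            "pathway_id": ids,
            "latent": [result.adjusted_p[p] <= alpha for p in ids],
            "centrality": [result.scores[p] for p in ids],
        }
    )
    if enrich_rows is not None and len(enrich_rows):
        er = enrich_rows.rename(columns={"set_id": "pathway_id", "qvalue": "enrichment_q"})
        if er["pathway_id"].duplicated().any():
            dups = sorted(er.loc[er["pathway_id"].duplicated(), "pathway_id"])
            raise DataError(f"duplicate set ids in enrichment table: {dups[:5]}")
        er = er[[c for c in ("pathway_id", "name", "rich_ratio", "enrichment_q") if c in er.columns]]
        nodes = nodes.merge(er, on="pathway_id", how="left")
    for col in ("name", "rich_ratio", "enrichment_q"):
        if col not in nodes.columns:
            nodes[col] = np.nan
    nodes = nodes[NODE_COLUMNS]
    return nodes.sort_values("pathway_id", kind="mergesort").reset_index(drop=True)


def _fmt(v) -> str:
    if isinstance(v, float):
        if np.isnan(v):
            return NA
        return f"{v:.6g}"
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if pd.isna(v):
        return NA
    return str(v)


def write_graph(
    edges: Iterable[NetworkEdge],
    nodes: pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
) -> list[Path]:
    """Write the network in one of: ``tsv`` (edge + node bundle), ``sif``,
    ``graphml``.  Output bytes are deterministic for a fixed input: rows
    are emitted in sorted order and floats at 6 significant digits.
    Returns the list of files written.
    """
    path = Path(path)
    edges = sorted(edges, key=lambda e: (e.source, e.target))
    edge_nodes = {e.source for e in edges} | {e.target for e in edges}
    known = set(nodes["pathway_id"])
    orphan = edge_nodes - known
    if orphan:
        raise DataError(f"edge endpoint(s) missing from node table: {sorted(orphan)[:5]}")

    if format == "tsv":
        edge_path = path.with_suffix(".edges.tsv")
        node_path = path.with_suffix(".nodes.tsv")
        with edge_path.open("w") as fh:
            fh.write("source\ttarget\tweight\n")
            for e in edges:
                fh.write(f"{e.source}\t{e.target}\t{e.weight:.6g}\n")
        with node_path.open("w") as fh:
            fh.write("\t".join(NODE_COLUMNS) + "\n")
            for row in nodes.itertuples(index=False):
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
        return [edge_path, node_path]

    if format == "sif":
        sif_path = path.with_suffix(".sif")
        with sif_path.open("w") as fh:
            for e in edges:
                fh.write(f"{e.source} pp {e.target}\n")
        return [sif_path]

    if format == "graphml":
        g = nx.Graph()
        for row in nodes.itertuples(index=False):
            attrs = {c: _fmt(v) for c, v in zip(NODE_COLUMNS[1:], row[1:])}
            g.add_node(row.pathway_id, **attrs)
        for e in edges:
            g.add_edge(e.source, e.target, weight=float(f"{e.weight:.6g}"))
        gml_path = path.with_suffix(".graphml")
        nx.write_graphml(g, gml_path)
        return [gml_path]

    raise ConfigError(f"unknown format {format!r}; expected tsv, sif or graphml")


def read_edge_tsv(path: str | Path) -> list[NetworkEdge]:
    """Read back an edge TSV written by :func:`write_graph`."""
    df = pd.read_csv(path, sep="\t")
    return [
        NetworkEdge(str(r.source), str(r.target), float(r.weight))
        for r in df.itertuples(index=False)
    ]
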