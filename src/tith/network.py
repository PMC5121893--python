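"""Parsing and restriction of undirected protein-interaction networks.

Networks are plain :class:`networkx.Graph` objects over gene symbols —
undirected, simple (no self-loops, no parallel edges).  An optional numeric
confidence column (e.g. a STRING combined score) may be used to filter
edges at load time, but edges are always *unweighted* in the divergence
math: the mass-action neighbor probabilities depend on expression only.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["load_network", "restrict_to_genes", "neighbor_list"]


def load_network(
    path,
    score_column: int | None = None,
    min_score: float | None = None,
    header: bool = False,
) -> nx.Graph:
    """Load an undirected edge list from a 2+ column TSV.

    Parameters
    ----------
    path
        TSV with columns geneA, geneB[, score, ...].
    score_column
        0-based index of a numeric confidence column; the filter applies only
        if both ``score_column`` and ``min_score`` are given.
    min_score
        Minimum score an edge must reach to be retained (inclusive).
    header
        Whether the first line is a header (explicit flag, no sniffing).

    Returns
    -------
    networkx.Graph
        Simple undirected graph; self-loops dropped (count logged), duplicate
        edges merged.
    """
    table = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least 2 columns, found {table.shape[1]}")
    if table.shape[0] == 0:
        raise ValueError(f"{path}: empty edge list")

    a = table.iloc[:, 0].astype(str)
    b = table.iloc[:, 1].astype(str)
    if score_column is not None and min_score is not None:
        if score_column >= table.shape[1]:
            raise ValueError(
                f"{path}: score_column {score_column} out of range for "
                f"{table.shape[1]} columns"
            )
        scores = pd.to_numeric(table.iloc[:, score_column], errors="raise")
        keep = (scores >= min_score).to_numpy()
        a, b = a[keep], b[keep]

    graph = nx.Graph()
    graph.add_edges_from(zip(a, b))
    loops = list(nx.selfloop_edges(graph))
    if loops:
        logger.warning("%s: dropped %d self-loop(s)", path, len(loops))
        graph.remove_edges_from(loops)
    graph.remove_nodes_from(list(nx.isolates(graph)))
    if graph.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges remain after filtering (min_score={min_score})")
    return graph


def restrict_to_genes(net: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``nodes ∩ genes`` with isolated nodes removed.

    Idempotent; logs the number of dropped nodes.  A restriction that leaves
    no nodes returns an empty graph with a warning (callers that need a
    non-empty universe raise their own errors).
    """
    keep = set(genes) & set(net.nodes)
    sub = nx.Graph(net.subgraph(keep))
    sub.remove_nodes_from(list(nx.isolates(sub)))
    dropped = net.number_of_nodes() - sub.number_of_nodes()
    if dropped:
        logger.info("restrict_to_genes: dropped %d node(s)", dropped)
    if sub.number_of_nodes() == 0:
        logger.warning("restrict_to_genes: restriction produced an empty graph")
    return sub


def neighbor_list(net: nx.Graph, gene: str) -> list[str]:
    """Deterministic (lexicographically sorted) neighbor list of a gene."""
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    return sorted(net.neighbors(gene))
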