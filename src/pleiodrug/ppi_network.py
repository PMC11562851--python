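"""Protein-protein interaction network loading and degree binning.

The network is a STRING-style undirected graph: edges carry an integer
``combined_score`` in [0, 1000], and only high-confidence edges
(score >= 700 by default, i.e. STRING's 0.7) are retained.  Protein
identifiers are mapped to Entrez gene IDs through a STRING alias table;
proteins without an Entrez alias are dropped.  Degree quartile bins are the
basis of the degree-matched permutation null used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("pleiodrug")

__all__ = ["PPINetwork", "load_string_network", "assign_degree_bins", "quartile_bins"]


@dataclass
class PPINetwork:
    """Undirected confidence-filtered gene network keyed by Entrez ID.

    ``degree_bin`` maps each node to a quartile bin in {1, 2, 3, 4}
    (1 = lowest degree); it is empty until :func:`assign_degree_bins`
    has been applied.
    """

    graph: nx.Graph
    degree_bin: dict[int, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    def degree(self, node: int) -> int:
        return self.graph.degree[node]

    def bin_members(self, bin_id: int) -> list[int]:
        """Nodes in a degree bin, sorted for reproducibility."""
        return sorted(n for n, b in self.degree_bin.items() if b == bin_id)

    def summary(self) -> dict:
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_bins": len(set(self.degree_bin.values())),
        }


def read_alias_table(alias_path, entrez_source: str = "Entrez_Gene") -> dict[str, int]:
    """Map STRING protein IDs to Entrez IDs using rows with the given source tag."""
    df = pd.read_csv(
        alias_path,
        sep="\t",
        comment=None,
        header=0,
        dtype=str,
    )
    df.columns = [c.lstrip("#").strip() for c in df.columns]
    required = {"string_protein_id", "alias", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"alias file missing column(s): {sorted(missing)}")
    sel = df[df["source"] == entrez_source]
    mapping: dict[str, int] = {}
    for pid, alias in zip(sel["string_protein_id"], sel["alias"]):
        try:
            mapping[pid] = int(alias)
        except (TypeError, ValueError):
            continue
    return mapping


def load_string_network(
    links_path,
    alias_path,
    min_score: int = 700,
    entrez_source: str = "Entrez_Gene",
) -> PPINetwork:
    """Load a STRING-format links file into a clean Entrez-keyed graph.

    Edges with ``combined_score`` below ``min_score`` are dropped, self-loops
    removed, duplicate edges collapsed keeping the maximum score, and
    proteins lacking an Entrez alias discarded.  When several proteins map
    to one Entrez ID the nodes are merged and their edges unioned.
    """
    links = pd.read_csv(links_path, sep=r"\s+", header=0)
    for col in ("protein1", "protein2", "combined_score"):
        if col not in links.columns:
            raise ValueError(f"links file missing column: {col}")
    mapping = read_alias_table(alias_path, entrez_source)

    links = links[links["combined_score"] >= min_score]
    g = nx.Graph()
    n_unmapped = 0
    n_loops = 0
    for p1, p2, score in links.itertuples(index=False):
        e1 = mapping.get(p1)
        e2 = mapping.get(p2)
        if e1 is None or e2 is None:
            n_unmapped += 1
            continue
        if e1 == e2:
            n_loops += 1
            continue
        score = int(score)
        if g.has_edge(e1, e2):
            if score > g[e1][e2]["score"]:
                g[e1][e2]["score"] = score
        else:
            g.add_edge(e1, e2, score=score)
    if n_unmapped:
        logger.info("dropped %d edges touching proteins without an Entrez alias", n_unmapped)
    if n_loops:
        logger.info("removed %d self-loops", n_loops)
    logger.info(
        "PPI network: %d nodes, %d edges (combined_score >= %d)",
        g.number_of_nodes(),
        g.number_of_edges(),
        min_score,
    )
    return PPINetwork(graph=g)


def quartile_bins(degrees: dict[int, int]) -> dict[int, int]:
    """Quartile bins {1..4} for a node -> degree map.

    Nodes are ordered by (degree, Entrez ID) and split at rank quartiles;
    nodes sharing a degree always share a bin (the bin of the first
    occurrence in that order), so bins are deterministic and tie-consistent.
    """
    nodes = sorted(degrees, key=lambda n: (degrees[n], n))
    n = len(nodes)
    provisional = {node: (4 * i) // n + 1 for i, node in enumerate(nodes)}
    degree_bin_of: dict[int, int] = {}
    bins: dict[int, int] = {}
    for node in nodes:
        d = degrees[node]
        if d not in degree_bin_of:
            degree_bin_of[d] = provisional[node]
        bins[node] = degree_bin_of[d]
    return bins


def assign_degree_bins(net: PPINetwork) -> PPINetwork:
    """Partition nodes into four degree-quartile bins (in place; also returned).

    See :func:`quartile_bins` for the tie-handling rule; a network with
    fewer than four distinct degrees yields degenerate bins with a warning.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot bin an empty network")
    bins = quartile_bins({n: net.graph.degree[n] for n in net.graph.nodes})
    n_distinct = len(set(bins.values()))
    if n_distinct < 4:
        logger.warning(
            "degenerate degree binning: only %d distinct bin(s) "
            "(fewer than 4 distinct degrees in the network)",
            n_distinct,
        )
    net.degree_bin = bins
    return net


def write_network_tables(net: PPINetwork, edge_path, node_path) -> None:
    """Dump edge list and node attributes as TSV for inspection."""
    edges = pd.DataFrame(
        [(min(u, v), max(u, v), d["score"]) for u, v, d in net.graph.edges(data=True)],
        columns=["entrez1", "entrez2", "combined_score"],
    ).sort_values(["entrez1", "entrez2"])
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        {
            "entrez": sorted(net.graph.nodes),
            "degree": [net.graph.degree[n] for n in sorted(net.graph.nodes)],
            "degree_bin": [net.degree_bin.get(n, 0) for n in sorted(net.graph.nodes)],
        }
    )
    nodes.to_csv(node_path, sep="\t", index=False)
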