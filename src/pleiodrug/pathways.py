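"""Canonical pathway gene sets: GMT parsing and restriction to the network.

Pathways are MSigDB-style named gene sets (BioCarta, KEGG, Reactome, PID,
WikiPathways in real data).  Only membership is used downstream — a pathway
is scored by the mean network-propagation score of its member genes — so the
collection is just a mapping from pathway name to a set of Entrez IDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .ppi_network import PPINetwork

logger = logging.getLogger("pleiodrug")

__all__ = ["PathwayCollection", "read_gmt", "restrict_to_network"]

_SOURCE_PREFIXES = ("BIOCARTA", "KEGG", "REACTOME", "PID", "WP")


def _source_tag(name: str) -> str:
    head = name.split("_", 1)[0].upper()
    return head if head in _SOURCE_PREFIXES else "OTHER"


@dataclass
class PathwayCollection:
    """Named gene sets with a source-database tag per pathway."""

    pathways: dict[str, frozenset[int]]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.source:
            self.source = {name: _source_tag(name) for name in self.pathways}

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def names(self) -> list[str]:
        return sorted(self.pathways)

    def gene_universe(self) -> set[int]:
        universe: set[int] = set()
        for members in self.pathways.values():
            universe |= members
        return universe

    def subset(self, names) -> "PathwayCollection":
        names = set(names)
        return PathwayCollection(
            pathways={k: v for k, v in self.pathways.items() if k in names},
            source={k: v for k, v in self.source.items() if k in names},
        )


def read_gmt(path, alias: dict[str, int] | None = None) -> PathwayCollection:
    """Parse a GMT file (name, description, tab-separated members).

    Members are Entrez IDs by default; pass ``alias`` (symbol -> Entrez) for
    the gene-symbol GMT variant.  Duplicate members within a line are
    deduplicated; a line with fewer than 3 fields is a fatal error.
    """
    pathways: dict[str, frozenset[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, _desc, *members = fields
            genes: set[int] = set()
            for m in members:
                if not m:
                    continue
                if alias is not None:
                    if m in alias:
                        genes.add(alias[m])
                else:
                    genes.add(int(m))
            pathways[name] = frozenset(genes)
    return PathwayCollection(pathways=pathways)


def restrict_to_network(
    collection: PathwayCollection, net: PPINetwork, min_size: int = 1
) -> PathwayCollection:
    """Drop member genes absent from the network; drop pathways below min_size."""
    nodes = net.nodes
    kept: dict[str, frozenset[int]] = {}
    n_dropped = 0
    for name, members in collection.pathways.items():
        restricted = frozenset(members & nodes)
        if len(restricted) >= min_size and restricted:
            kept[name] = restricted
        else:
            n_dropped += 1
    if n_dropped:
        logger.info(
            "dropped %d pathway(s) below %d network-mapped member(s)", n_dropped, min_size
        )
    return PathwayCollection(
        pathways=kept, source={k: collection.source.get(k, _source_tag(k)) for k in kept}
    )


def write_pathway_table(collection: PathwayCollection, path) -> None:
    df = pd.DataFrame(
        {
            "pathway": collection.names(),
            "source": [collection.source[n] for n in collection.names()],
            "n_genes": [len(collection.pathways[n]) for n in collection.names()],
            "genes": [
                ";".join(map(str, sorted(collection.pathways[n]))) for n in collection.names()
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
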