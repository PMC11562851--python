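import json

import networkx as nx
import pytest

from pleiodrug import (
    PPINetwork,
    SyntheticConfig,
    assign_degree_bins,
    generate_all,
    load_string_network,
)

# Desk-scale study conditions used by the unit tests; the acceptance tests use
# the generator's defaults.
SMALL_CFG = SyntheticConfig(
    seed=7,
    n_genes=400,
    n_pathways=30,
    pathway_size_range=(8, 15),
    n_drugs=20,
    n_loci=12,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_bundle")
    paths = generate_all(SMALL_CFG, outdir)
    with open(paths["truth"]) as fh:
        truth = json.load(fh)
    return {"cfg": SMALL_CFG, "paths": paths, "truth": truth}


@pytest.fixture(scope="session")
def small_net(small_bundle):
    net = load_string_network(
        small_bundle["paths"]["links"], small_bundle["paths"]["aliases"]
    )
    return assign_degree_bins(net)


def make_net(graph: nx.Graph) -> PPINetwork:
    """Wrap a bare networkx graph as a binned PPINetwork for toy tests."""
    for _, _, d in graph.edges(data=True):
        d.setdefault("score", 900)
    return assign_degree_bins(PPINetwork(graph=graph))
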