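"""Personalized PageRank, pathway scoring and the degree-matched
permutation test."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pleiodrug import (
    PPREngine,
    PPRParams,
    link_seeds_to_pathways,
    link_targets_to_pathways,
    pathway_score,
    permutation_p,
    personalized_pagerank,
)
from pleiodrug.pathways import PathwayCollection
from tests.conftest import make_net


def solve_ppr(graph, seed, restart):
    """Direct linear-solve oracle: s = restart * (I - (1-restart) W^T)^-1 e."""
    nodes = sorted(graph)
    idx = {n: i for i, n in enumerate(nodes)}
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    deg = adj.sum(axis=1)
    walk = np.zeros_like(adj)
    for i in range(len(nodes)):
        if deg[i] > 0:
            walk[i] = adj[i] / deg[i]
        else:
            walk[i, idx[seed]] = 1.0
    n = len(nodes)
    e = np.zeros(n)
    e[idx[seed]] = 1.0
    s = restart * np.linalg.solve(np.eye(n) - (1 - restart) * walk.T, e)
    return pd.Series(s, index=nodes)


class TestPersonalizedPagerank:
    def test_two_node_closed_form(self):
        net = make_net(nx.path_graph([1, 2]))
        scores = personalized_pagerank(net, 1, PPRParams(restart=0.8))
        assert scores[1] == pytest.approx(1 / (2 - 0.8), abs=1e-9)
        assert scores[2] == pytest.approx(0.2 / 1.2, abs=1e-9)

    def test_complete_graph_symmetry(self):
        net = make_net(nx.complete_graph([1, 2, 3, 4]))
        scores = personalized_pagerank(net, 1)
        assert scores[2] == pytest.approx(scores[3], abs=1e-12)
        assert scores[3] == pytest.approx(scores[4], abs=1e-12)

    def test_high_restart_concentrates_on_seed(self):
        net = make_net(nx.path_graph([1, 2, 3]))
        scores = personalized_pagerank(net, 1, PPRParams(restart=0.9999))
        assert scores[1] == pytest.approx(1.0, abs=1e-3)

    def test_sums_to_one_and_nonnegative(self, small_net):
        node = sorted(small_net.nodes)[10]
        scores = personalized_pagerank(small_net, node)
        assert scores.sum() == pytest.approx(1.0, abs=1e-8)
        assert (scores >= 0).all()

    def test_matches_linear_solve_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            g = nx.gnp_random_graph(25, 0.15, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {n: n + 1 for n in g})
            net = make_net(g)
            seed = int(rng.choice(sorted(net.nodes)))
            mine = personalized_pagerank(net, seed)
            oracle = solve_ppr(net.graph, seed, 0.8)
            assert np.abs(mine - oracle).max() < 1e-8

    def test_matches_networkx_pagerank(self):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        g = nx.relabel_nodes(g, {n: n + 1 for n in g})
        net = make_net(g)
        seed = sorted(net.nodes)[0]
        mine = personalized_pagerank(net, seed, PPRParams(restart=0.8, tol=1e-12))
        ref = nx.pagerank(
            net.graph, alpha=0.2, personalization={seed: 1.0}, tol=1e-12, max_iter=500
        )
        for node, value in ref.items():
            assert mine[node] == pytest.approx(value, abs=1e-6)

    def test_relabel_invariance(self):
        g = nx.gnp_random_graph(15, 0.25, seed=9)
        g = nx.relabel_nodes(g, {n: n + 1 for n in g})
        mapping = {n: n + 1000 for n in g}
        net1, net2 = make_net(g.copy()), make_net(nx.relabel_nodes(g, mapping))
        s1 = personalized_pagerank(net1, 5)
        s2 = personalized_pagerank(net2, 1005)
        for node in s1.index:
            assert s1[node] == pytest.approx(s2[node + 1000], abs=1e-12)

    def test_unknown_seed_errors_with_name(self):
        net = make_net(nx.path_graph([1, 2]))
        with pytest.raises(ValueError, match="777"):
            personalized_pagerank(net, 777)


class TestPathwayScore:
    def test_mean_of_members(self):
        scores = pd.Series({1: 0.5, 2: 0.3, 3: 0.2})
        assert pathway_score(scores, {2, 3}) == pytest.approx(0.25)

    def test_all_nodes_gives_uniform(self):
        net = make_net(nx.path_graph([1, 2, 3, 4]))
        scores = personalized_pagerank(net, 1)
        assert pathway_score(scores, set(scores.index)) == pytest.approx(0.25, abs=1e-9)

    def test_singleton(self):
        scores = pd.Series({1: 0.5, 2: 0.3})
        assert pathway_score(scores, {2}) == pytest.approx(0.3)

    def test_empty_pathway_errors(self):
        with pytest.raises(ValueError):
            pathway_score(pd.Series({1: 1.0}), set())

    def test_adding_higher_scoring_member_never_decreases_mean(self):
        scores = pd.Series({1: 0.5, 2: 0.3, 3: 0.2, 4: 0.05})
        members = {3, 4}
        base = pathway_score(scores, members)
        for extra in (1, 2):
            if scores[extra] >= base:
                assert pathway_score(scores, members | {extra}) >= base


def star_net():
    # hub 1 with leaves 2..4: leaves are mutually symmetric bin mates
    return make_net(nx.star_graph([1, 2, 3, 4]))


class TestPermutation:
    def test_observed_beats_all_permuted(self):
        net = star_net()
        params = PPRParams(n_perm=100, rng_seed=1)
        res = permutation_p(net, 2, "self", {2}, params)
        # only leaf 2 scores itself highly; permuted leaves score it low
        assert res.perm_count_ge == 0 and res.p_perm == 0.0

    def test_add_one_estimator_floor(self):
        net = star_net()
        params = PPRParams(n_perm=100, rng_seed=1, add_one_p=True)
        res = permutation_p(net, 2, "self", {2}, params)
        assert res.p_perm == pytest.approx(1 / 101)

    def test_observed_tied_with_all_permuted_gives_one(self):
        net = star_net()
        params = PPRParams(n_perm=100, rng_seed=1)
        # every leaf scores the hub identically: all permuted means tie >= observed
        res = permutation_p(net, 2, "hub", {1}, params)
        assert res.p_perm == 1.0

    def test_matches_enumeration_oracle(self):
        g = nx.gnp_random_graph(30, 0.2, seed=13)
        g = nx.relabel_nodes(g, {n: n + 1 for n in g})
        net = make_net(g)
        members = frozenset({3, 9, 17, 25})
        seed = 12
        params = PPRParams(n_perm=50, rng_seed=4)
        res = permutation_p(net, seed, "pw", members, params)
        # brute force: score every bin mate via the independent solver
        pool = [n for n in net.bin_members(net.degree_bin[seed]) if n != seed]
        obs = pathway_score(solve_ppr(net.graph, seed, 0.8), members)
        pool_scores = [
            pathway_score(solve_ppr(net.graph, q, 0.8), members) for q in pool
        ]
        frac = float(np.mean([s >= obs for s in pool_scores]))
        mc_sd = np.sqrt(max(frac * (1 - frac), 0.01) / params.n_perm)
        assert abs(res.p_perm - frac) <= 4 * mc_sd

    def test_deterministic_and_order_independent(self, small_net, small_bundle):
        truth = small_bundle["truth"]
        seeds = truth["shared_genes"][:3]
        names = truth["planted_pathways"][:2]
        coll = PathwayCollection(
            pathways={n: frozenset(truth["modules"][n]) for n in names}
        )
        params = PPRParams(n_perm=50, rng_seed=9)
        table = link_seeds_to_pathways(small_net, seeds, coll, params)
        # fresh engine, pairs evaluated one by one in reverse order
        engine = PPREngine(small_net, params)
        for row in table.iloc[::-1].itertuples(index=False):
            res = engine.permutation_result(
                row.seed, row.pathway, coll.pathways[row.pathway]
            )
            assert res.p_perm == row.p_perm
            assert res.observed == pytest.approx(row.observed, abs=1e-12)

    def test_small_bin_falls_back_to_nearest(self, caplog):
        # hub has a singleton degree bin; permutation must still run
        net = make_net(nx.star_graph([1, 2, 3, 4, 5, 6, 7, 8]))
        params = PPRParams(n_perm=20, rng_seed=0)
        res = permutation_p(net, 1, "pw", {2, 3}, params)
        assert 0.0 <= res.p_perm <= 1.0


class TestLinkageTables:
    def toy(self):
        g = nx.gnp_random_graph(20, 0.3, seed=2)
        g = nx.relabel_nodes(g, {n: n + 1 for n in g})
        net = make_net(g)
        coll = PathwayCollection(
            pathways={
                "A": frozenset({2, 3, 4}),
                "B": frozenset({5, 6}),
                "C": frozenset({7, 8, 9}),
            }
        )
        return net, coll

    def test_bonferroni_family_seeds_times_pathways(self):
        net, coll = self.toy()
        params = PPRParams(n_perm=20, rng_seed=3)
        table = link_seeds_to_pathways(net, [1, 10], coll, params)
        assert len(table) == 6
        expected = np.minimum(1.0, table["p_perm"] * 6)
        assert np.allclose(table["p_adj"], expected)
        assert (table["significant"] == (table["p_adj"] < 0.05)).all()

    def test_empty_seed_set(self):
        net, coll = self.toy()
        table = link_seeds_to_pathways(net, [], coll, PPRParams(n_perm=10))
        assert len(table) == 0

    def test_off_network_seeds_dropped(self):
        net, coll = self.toy()
        table = link_seeds_to_pathways(net, [1, 999], coll, PPRParams(n_perm=10, rng_seed=1))
        assert set(table["seed"]) == {1}
        # family size counts only in-network seeds
        assert np.allclose(table["p_adj"], np.minimum(1, table["p_perm"] * 3))

    def test_target_stage_family_is_target_count(self):
        net, coll = self.toy()
        params = PPRParams(n_perm=20, rng_seed=5)
        table = link_targets_to_pathways(net, [1, 10, 15], coll, params)
        assert np.allclose(table["p_adj"], np.minimum(1, table["p_perm"] * 3))

    def test_off_network_target_row_absent(self):
        net, coll = self.toy()
        table = link_targets_to_pathways(net, [1, 999], coll, PPRParams(n_perm=10, rng_seed=1))
        assert 999 not in set(table["seed"])


def test_include_seed_flag_changes_observed(small_net, small_bundle):
    truth = small_bundle["truth"]
    name = truth["planted_pathways"][0]
    members = frozenset(truth["modules"][name])
    anchor = truth["anchors"][0]
    with_seed = permutation_p(
        small_net, anchor, name, members, PPRParams(n_perm=5, rng_seed=0, include_seed=True)
    )
    without = permutation_p(
        small_net, anchor, name, members, PPRParams(n_perm=5, rng_seed=0, include_seed=False)
    )
    assert with_seed.observed > without.observed
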