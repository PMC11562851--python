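"""Personalized-PageRank linkage of seed genes to canonical pathways with a
degree-matched permutation null.

The core statistic: starting a random walk at a *seed* gene which restarts
at the seed with probability ``restart`` (default 0.8) after every step, the
stationary distribution assigns each network gene a connectivity score; a
pathway is scored by the mean over its members.  Significance is assessed
against a null of seeds drawn uniformly (with replacement) from the same
degree-quartile bin as the observed seed: the permutation p-value is the
fraction of permuted pathway means at least as large as the observed one,
and is then Bonferroni-adjusted over the family of tests (seeds x pathways
in the gene stage; distinct drug targets in the drug stage).

The permutation p-value can be exactly 0 when the observed score beats
every permuted draw; the add-one estimator (1+c)/(1+N), which cannot reach
0, is available via ``PPRParams.add_one_p`` but is off by default because a
Bonferroni family larger than ~ n_perm/20 could then never reach adjusted
significance at 0.05.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pathways import PathwayCollection
from .ppi_network import PPINetwork, assign_degree_bins

logger = logging.getLogger("pleiodrug")

__all__ = [
    "PPRParams",
    "PPREngine",
    "personalized_pagerank",
    "pathway_score",
    "permutation_p",
    "link_seeds_to_pathways",
    "link_targets_to_pathways",
]


@dataclass
class PPRParams:
    """Tuning knobs for propagation and the permutation null.

    restart        probability of returning to the seed after each step
    tol            L1 convergence tolerance of the power iteration
    max_iter       iteration cap (non-convergence is an error)
    n_perm         number of degree-matched permuted seeds
    rng_seed       base seed; each (seed gene, pathway) pair gets its own
                   substream so results do not depend on evaluation order
    add_one_p      use the add-one estimator (1+c)/(1+N) instead of c/N
    include_seed   include the seed's own score in the pathway mean when the
                   seed is a member
    alpha          significance threshold on the Bonferroni-adjusted p
    """

    restart: float = 0.8
    tol: float = 1e-10
    max_iter: int = 1000
    n_perm: int = 1000
    rng_seed: int = 0
    add_one_p: bool = False
    include_seed: bool = True
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.restart < 1.0:
            raise ValueError("restart must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class LinkageResult:
    seed: int
    pathway: str
    observed: float
    perm_count_ge: int
    p_perm: float
    p_adj: float | None = None
    significant: bool | None = None


def _pair_rng(rng_seed: int, seed_gene: int, pathway: str) -> np.random.Generator:
    """Stable per-(seed, pathway) RNG substream, independent of call order."""
    digest = hashlib.blake2b(
        f"{rng_seed}|{seed_gene}|{pathway}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))


class PPREngine:
    """Caches propagation vectors and per-bin pathway scores for one network."""

    def __init__(self, net: PPINetwork, params: PPRParams):
        if not net.degree_bin:
            assign_degree_bins(net)
        self.net = net
        self.params = params
        self.nodes = np.array(sorted(net.graph.nodes))
        self.index = {int(g): i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        adj = nx_to_csr(net, self.nodes, self.index)
        deg = np.asarray(adj.sum(axis=1)).ravel()
        self._dangling = deg == 0.0
        safe = np.where(deg > 0, deg, 1.0)
        # column-scaled adjacency: (A @ (s / deg)) is one walk step
        self._adj = adj
        self._inv_deg = 1.0 / safe
        self._vec_cache: dict[int, np.ndarray] = {}
        self._bin_pool: dict[int, np.ndarray] = {}
        self._bin_score_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
        self.n_nodes = n

    # -- propagation ---------------------------------------------------
    def vector(self, seed_gene: int) -> np.ndarray:
        """Personalized-PageRank score vector for a seed gene (cached)."""
        idx = self.index.get(int(seed_gene))
        if idx is None:
            raise ValueError(f"seed gene {seed_gene} is not in the network")
        cached = self._vec_cache.get(idx)
        if cached is not None:
            return cached
        p = self.params
        e = np.zeros(self.n_nodes)
        e[idx] = 1.0
        s = e.copy()
        for _ in range(p.max_iter):
            step = self._adj @ (s * self._inv_deg)
            # walk mass on zero-degree nodes teleports back to the seed
            if self._dangling.any():
                step[idx] += s[self._dangling].sum()
            s_new = p.restart * e + (1.0 - p.restart) * step
            resid = np.abs(s_new - s).sum()
            s = s_new
            if resid < p.tol:
                break
        else:
            raise RuntimeError(
                f"personalized PageRank did not converge after {p.max_iter} "
                f"iterations (residual {resid:.3e})"
            )
        self._vec_cache[idx] = s
        return s

    # -- permutation machinery -----------------------------------------
    def bin_pool(self, bin_id: int) -> np.ndarray:
        pool = self._bin_pool.get(bin_id)
        if pool is None:
            pool = np.array(self.net.bin_members(bin_id))
            self._bin_pool[bin_id] = pool
        return pool

    def _pool_for_seed(self, seed_gene: int) -> np.ndarray:
        """Degree-bin candidate pool for a seed, excluding the seed itself.

        Bins with fewer than 2 other members fall back to the nearest
        non-empty bin.
        """
        bin_id = self.net.degree_bin[seed_gene]
        pool = self.bin_pool(bin_id)
        pool = pool[pool != seed_gene]
        if len(pool) >= 2:
            return pool
        present = sorted(set(self.net.degree_bin.values()))
        for other in sorted(present, key=lambda b: (abs(b - bin_id), b)):
            if other == bin_id:
                continue
            alt = self.bin_pool(other)
            alt = alt[alt != seed_gene]
            if len(alt) >= 2:
                logger.warning(
                    "degree bin %d too small for seed %d; using bin %d",
                    bin_id,
                    seed_gene,
                    other,
                )
                return alt
        return pool  # degenerate single-bin network

    def _member_scores(
        self, genes: np.ndarray, member_idx: np.ndarray, cache_key: tuple | None
    ) -> np.ndarray:
        """Mean pathway score for propagation from each gene in ``genes``."""
        if cache_key is not None:
            hit = self._bin_score_cache.get(cache_key)
            if hit is not None and np.array_equal(hit[0], genes):
                return hit[1]
        scores = np.empty(len(genes))
        for i, g in enumerate(genes):
            scores[i] = self.vector(int(g))[member_idx].mean()
        if cache_key is not None:
            self._bin_score_cache[cache_key] = (genes, scores)
        return scores

    def permutation_result(
        self, seed_gene: int, pathway_name: str, members: frozenset[int]
    ) -> LinkageResult:
        p = self.params
        members_eff = set(members)
        excluded = None
        if not p.include_seed and seed_gene in members_eff:
            members_eff.discard(seed_gene)
            excluded = seed_gene
        if not members_eff:
            raise ValueError(f"pathway {pathway_name!r} has no members to score")
        member_idx = np.array(sorted(self.index[g] for g in members_eff))

        observed = float(self.vector(seed_gene)[member_idx].mean())

        pool = self._pool_for_seed(seed_gene)
        bin_id = self.net.degree_bin[seed_gene]
        # pool scores are cached per (bin, pathway); the seed's own entry is
        # masked out afterwards so the cache is reusable across seeds
        full_pool = self.bin_pool(bin_id)
        cache_key = (bin_id, pathway_name, excluded)
        full_scores = self._member_scores(full_pool, member_idx, cache_key)
        mask = full_pool != seed_gene
        if mask.sum() >= 2:
            pool, pool_scores = full_pool[mask], full_scores[mask]
        else:
            pool_scores = self._member_scores(pool, member_idx, None)

        rng = _pair_rng(p.rng_seed, seed_gene, pathway_name)
        draws = rng.integers(0, len(pool), size=p.n_perm)
        perm_means = pool_scores[draws]
        count_ge = int((perm_means >= observed).sum())
        if p.add_one_p:
            p_perm = (1 + count_ge) / (1 + p.n_perm)
        else:
            p_perm = count_ge / p.n_perm
        return LinkageResult(
            seed=int(seed_gene),
            pathway=pathway_name,
            observed=observed,
            perm_count_ge=count_ge,
            p_perm=p_perm,
        )


def nx_to_csr(net: PPINetwork, nodes: np.ndarray, index: dict[int, int]) -> sp.csr_matrix:
    """Binary symmetric adjacency in CSR form (unweighted propagation)."""
    rows, cols = [], []
    for u, v in net.graph.edges:
        iu, iv = index[u], index[v]
        rows.extend((iu, iv))
        cols.extend((iv, iu))
    n = len(nodes)
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def personalized_pagerank(
    net: PPINetwork, seed_gene: int, params: PPRParams | None = None
) -> pd.Series:
    """Score vector of the restart walk from one seed, indexed by Entrez ID.

    Scores are non-negative and sum to 1; the fixed point solved is
    s = restart * e_seed + (1 - restart) * W^T s with W the row-stochastic
    transition matrix of the undirected, unweighted graph.
    """
    params = params or PPRParams()
    engine = PPREngine(net, params)
    vec = engine.vector(seed_gene)
    return pd.Series(vec, index=engine.nodes)


def pathway_score(scores: pd.Series, members) -> float:
    """Arithmetic mean of propagation scores over pathway members."""
    members = sorted(members)
    if not members:
        raise ValueError("cannot score an empty pathway")
    return float(scores.loc[members].mean())


def permutation_p(
    net: PPINetwork,
    seed_gene: int,
    pathway_name: str,
    members,
    params: PPRParams | None = None,
    engine: PPREngine | None = None,
) -> LinkageResult:
    """Degree-matched permutation test for one (seed, pathway) pair."""
    params = params or PPRParams()
    engine = engine or PPREngine(net, params)
    return engine.permutation_result(int(seed_gene), pathway_name, frozenset(members))


def _linkage_table(results: list[LinkageResult], m: int, alpha: float) -> pd.DataFrame:
    rows = []
    for r in results:
        p_adj = min(1.0, r.p_perm * m)
        rows.append(
            {
                "seed": r.seed,
                "pathway": r.pathway,
                "observed": r.observed,
                "perm_count_ge": r.perm_count_ge,
                "p_perm": r.p_perm,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["seed", "pathway", "observed", "perm_count_ge", "p_perm", "p_adj", "significant"],
    )


def link_seeds_to_pathways(
    net: PPINetwork,
    seeds,
    collection: PathwayCollection,
    params: PPRParams | None = None,
    engine: PPREngine | None = None,
) -> pd.DataFrame:
    """Test every (shared gene, pathway) pair.

    Bonferroni family = (# seeds in network) x (# pathways); ``significant``
    flags adjusted p < alpha.
    """
    params = params or PPRParams()
    engine = engine or PPREngine(net, params)
    in_net = sorted(s for s in set(seeds) if s in engine.index)
    dropped = set(seeds) - set(in_net)
    if dropped:
        logger.warning("dropping %d seed gene(s) absent from the network", len(dropped))
    names = collection.names()
    m = max(1, len(in_net) * len(names))
    results = [
        engine.permutation_result(s, name, collection.pathways[name])
        for s in in_net
        for name in names
    ]
    return _linkage_table(results, m, params.alpha)


def link_targets_to_pathways(
    net: PPINetwork,
    targets,
    shared_pathways: PathwayCollection,
    params: PPRParams | None = None,
    engine: PPREngine | None = None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Test every (drug target, shared pathway) pair.

    Bonferroni family = number of distinct network-mapped targets tested for
    the predisposing disease (pass ``family_size`` to widen the family when
    calling per drug); the shared-pathway set is fixed by the gene stage and
    is not counted again.
    """
    params = params or PPRParams()
    engine = engine or PPREngine(net, params)
    in_net = sorted(t for t in set(targets) if t in engine.index)
    dropped = set(targets) - set(in_net)
    if dropped:
        logger.info("dropping %d drug target(s) absent from the network", len(dropped))
    names = shared_pathways.names()
    m = family_size if family_size is not None else max(1, len(in_net))
    results = [
        engine.permutation_result(t, name, shared_pathways.pathways[name])
        for t in in_net
        for name in names
    ]
    return _linkage_table(results, max(1, m), params.alpha)
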