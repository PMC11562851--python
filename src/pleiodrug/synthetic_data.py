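"""Synthetic pipeline inputs with known planted structure.

Everything the pipeline consumes — a STRING-format network with alias
table, a GMT pathway file, gene annotations, a correlated-loci table,
gene-association and signed-regulation statistics, and drug tables — is
generated from one seeded configuration, so every stage is testable with no
downloads and a known ground truth.

The planted signal is a gene -> pathway -> drug chain.  Each planted
pathway is a dense network module (within-module edge probability 0.35)
anchored by one hub gene that is adjacent to every other member and has no
edges outside the module.  The anchor is placed inside a positively
correlated locus, given a tiny gene-association p-value and
direction-concordant z statistics (so it survives the shared-gene filters),
and is the target of the "true positive" drugs.  Because the anchor keeps
strictly more random-walk mass inside its pathway than any other network
gene of its degree bin, the propagation statistic recovers the chain.
Decoy drugs target random genes outside the modules; decoy locus genes
carry null association p-values or direction-discordant z so the filters
remove them.

Coordinates are 1-based with inclusive ends.  Identical configurations
produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SyntheticConfig",
    "generate_network",
    "generate_gene_annotations",
    "generate_pathways",
    "generate_disease_pair_artifacts",
    "generate_drug_tables",
    "generate_all",
]

_GENE_SPACING = 100_000
_GENE_LENGTH = 20_000
_N_SHARED = 7  # planted + unwired shared genes surviving all filters
_PHANTOM_TARGET = 999_999  # Entrez ID absent from annotations and network


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the real analysis loosely at desk scale: 2,000 genes,
    100 pathways of 10-50 genes, 60 drugs, positively and negatively
    correlated loci of ~150 kb.  ``frac_planted`` is the fraction of the
    shared-gene set wired into planted pathway modules (the rest survive
    the statistical filters but carry no network signal).
    """

    seed: int = 0
    n_genes: int = 2000
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (10, 50)
    n_drugs: int = 60
    targets_per_drug_range: tuple[int, int] = (1, 3)
    n_loci: int = 18
    locus_width_bp: int = 150_000
    frac_planted: float = 0.6
    edge_model: str = "scale-free"
    background_edge_density: float = 0.0005
    disease_pair: str = "PD-BC"

    def __post_init__(self):
        for name in ("n_genes", "n_pathways", "n_drugs", "n_loci", "locus_width_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_planted", "background_edge_density"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.edge_model not in ("scale-free", "erdos-renyi"):
            raise ValueError("edge_model must be 'scale-free' or 'erdos-renyi'")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid pathway_size_range")
        lo, hi = self.targets_per_drug_range
        if not (0 < lo <= hi):
            raise ValueError("invalid targets_per_drug_range")


class _Plan:
    """Complete ground truth for one configuration (internal)."""

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        n = cfg.n_genes
        self.entrez = np.arange(1001, 1001 + n)

        # -- gene coordinates: round-robin over 22 autosomes ------------
        chrom = (np.arange(n) % 22) + 1
        within = np.arange(n) // 22
        start = 1 + within * _GENE_SPACING
        end = start + _GENE_LENGTH - 1
        self.ann = pd.DataFrame(
            {"entrez": self.entrez, "chrom": chrom, "start": start, "end": end}
        )

        # -- loci: one per chromosome, hosting the gene at within-index 1
        per_chrom = np.bincount(chrom, minlength=23)
        usable_chroms = [c for c in range(1, 23) if per_chrom[c] >= 2]
        n_loci = min(cfg.n_loci, len(usable_chroms))
        n_pos = max(1, (2 * n_loci + 2) // 3)
        n_neg = n_loci - n_pos
        self.n_pos, self.n_neg = n_pos, n_neg

        def gene_at(c, j):
            sel = self.ann[(self.ann["chrom"] == c)].sort_values("start")
            return sel.iloc[j] if j < len(sel) else None

        loci = []
        self.locus_genes: list[dict] = []  # per locus: host, partial, before
        for k in range(n_loci):
            c = usable_chroms[k]
            host = gene_at(c, 1)
            locus_start = int(host["start"]) - 1000
            locus_end = locus_start + cfg.locus_width_bp - 1
            sign = 1 if k < n_pos else -1
            loci.append(
                {
                    "chrom": c,
                    "start": locus_start,
                    "end": locus_end,
                    "sign": sign,
                    "qvalue": round(float(rng.uniform(1e-4, 0.05)), 6),
                    "disease_pair": cfg.disease_pair,
                }
            )
            partial = gene_at(c, 2)
            self.locus_genes.append(
                {
                    "host": int(host["entrez"]),
                    "partial": int(partial["entrez"])
                    if partial is not None and int(partial["start"]) <= locus_end
                    else None,
                    "before": int(gene_at(c, 0)["entrez"]),
                }
            )
        self.loci = pd.DataFrame(loci)

        # boundary genes: exactly 10,000 bp (maps) and 10,001 bp (does not)
        self.boundary_in = self.boundary_out = None
        if n_pos >= 2:
            for locus_idx, gap, attr in ((0, 10_000, "boundary_in"), (1, 10_001, "boundary_out")):
                g = self.locus_genes[locus_idx]["before"]
                locus_start = int(self.loci.iloc[locus_idx]["start"])
                self.ann.loc[self.ann["entrez"] == g, "end"] = locus_start - gap
                setattr(self, attr, g)

        # -- role assignment over positive loci --------------------------
        n_planted = min(int(round(cfg.frac_planted * _N_SHARED)), max(0, n_pos - 1))
        n_extra = min(_N_SHARED - n_planted, max(0, n_pos - n_planted - 1))
        self.anchors = [self.locus_genes[k]["host"] for k in range(n_planted)]
        self.extra_shared = [
            self.locus_genes[n_planted + k]["host"] for k in range(n_extra)
        ]
        # remaining positive-locus hosts: direction-discordant decoys
        self.discordant = [
            self.locus_genes[k]["host"] for k in range(n_planted + n_extra, n_pos)
        ]
        self.negative_plants = [
            self.locus_genes[k]["host"] for k in range(n_pos, n_loci)
        ]
        self.null_locus_decoys = [
            lg[role]
            for lg in self.locus_genes
            for role in ("partial",)
            if lg[role] is not None
        ]

        reserved = set(
            g["host"] for g in self.locus_genes
        ) | set(self.null_locus_decoys) | {g["before"] for g in self.locus_genes}
        free = [int(g) for g in rng.permutation([g for g in self.entrez if int(g) not in reserved])]

        # -- planted modules ---------------------------------------------
        lo = cfg.pathway_size_range[0]
        self.modules: list[list[int]] = []
        for k in range(n_planted):
            max_size = max(4, min(lo + 5, len(free) // max(1, n_planted - k) - 1))
            size = int(rng.integers(min(lo, max_size), max_size + 1))
            members = [free.pop() for _ in range(min(size - 1, len(free) - 1))]
            self.modules.append([self.anchors[k]] + members)

        # -- drugs ---------------------------------------------------------
        module_genes = {g for mod in self.modules for g in mod}
        free_targets = [g for g in free if g not in module_genes]
        n_tp = max(2, cfg.n_drugs // 5) if n_planted else 0
        t_lo, t_hi = cfg.targets_per_drug_range
        drugs = []
        for i in range(cfg.n_drugs):
            drug_id = f"DB{i:05d}"
            if i < n_tp:
                targets = {self.anchors[i % n_planted]}
                extra = int(rng.integers(0, max(1, t_hi - 1) + 1))
                while len(targets) < min(t_hi, 1 + extra) and free_targets:
                    targets.add(free_targets[int(rng.integers(0, len(free_targets)))])
                kind = "tp"
            elif i == n_tp:
                targets = {_PHANTOM_TARGET}  # off-network: never a candidate
                kind = "decoy"
            else:
                k = int(rng.integers(t_lo, t_hi + 1))
                targets = set()
                while len(targets) < k and free_targets:
                    targets.add(free_targets[int(rng.integers(0, len(free_targets)))])
                kind = "decoy"
            drugs.append(
                {
                    "drug_id": drug_id,
                    "name": f"drug_{i:02d}",
                    "indication": cfg.disease_pair.split("-")[0],
                    "targets": sorted(targets),
                    "kind": kind,
                }
            )
        self.drugs = drugs
        self.tp_drugs = [d["drug_id"] for d in drugs if d["kind"] == "tp"]
        self.decoy_drugs = [d["drug_id"] for d in drugs if d["kind"] == "decoy"]
        n_bc_tp = max(1, int(round(0.8 * n_tp))) if n_tp else 0
        self.bc_drugs = self.tp_drugs[:n_bc_tp] + self.decoy_drugs[1:3]

        # -- unmapped genes (no Entrez alias row) --------------------------
        drug_target_genes = {t for d in drugs for t in d["targets"]}
        eligible_unmapped = [
            g for g in free if g not in module_genes and g not in drug_target_genes
        ]
        self.unmapped = sorted(eligible_unmapped[:5])

        # -- network edges -------------------------------------------------
        self._build_edges(rng)

        # -- pathways ------------------------------------------------------
        self.pathways: dict[str, list[int]] = {}
        for k, mod in enumerate(self.modules):
            self.pathways[f"PLANTED_MODULE_{k:03d}"] = sorted(mod)
        lo, hi = cfg.pathway_size_range
        mapped = [int(g) for g in self.entrez if int(g) not in set(self.unmapped)]
        for k in range(cfg.n_pathways - len(self.modules)):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(mapped, size=min(size, len(mapped)), replace=False)
            self.pathways[f"RANDOM_SET_{k:03d}"] = sorted(int(g) for g in members)

        # -- gene statistics ----------------------------------------------
        self._build_stats(rng)

    def _build_edges(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        anchors = set(self.anchors)
        bg_genes = [int(g) for g in self.entrez if int(g) not in anchors]
        n_bg = len(bg_genes)
        order = rng.permutation(n_bg)
        bg_seed = int(rng.integers(0, 2**31 - 1))
        if cfg.edge_model == "scale-free":
            g_bg = nx.barabasi_albert_graph(n_bg, min(3, n_bg - 1), seed=bg_seed)
        else:
            g_bg = nx.gnp_random_graph(n_bg, cfg.background_edge_density, seed=bg_seed)
        edges: list[tuple[int, int]] = [
            (bg_genes[order[u]], bg_genes[order[v]]) for u, v in g_bg.edges
        ]
        if cfg.edge_model == "scale-free" and cfg.background_edge_density > 0:
            n_noise = int(cfg.background_edge_density * n_bg * (n_bg - 1) / 2)
            for _ in range(n_noise):
                u, v = rng.choice(n_bg, size=2, replace=False)
                edges.append((bg_genes[int(u)], bg_genes[int(v)]))
        # planted modules: anchor adjacent to every member and nothing else;
        # members densely interconnected (p = 0.35)
        for anchor, mod in zip(self.anchors, self.modules):
            members = [g for g in mod if g != anchor]
            for m in members:
                edges.append((anchor, m))
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if rng.random() < 0.35:
                        edges.append((members[i], members[j]))
        dedup = {}
        for u, v in edges:
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            dedup[key] = None
        self.design_edges = sorted(dedup)
        self.edge_scores = rng.integers(700, 1001, size=len(self.design_edges))

        # file-level noise exercising the loader
        n_dup = min(50, len(self.design_edges))
        dup_idx = rng.choice(len(self.design_edges), size=n_dup, replace=False)
        self.duplicate_edges = [
            (self.design_edges[i], int(rng.integers(700, self.edge_scores[i] + 1)))
            for i in sorted(dup_idx)
        ]
        n_low = max(5, cfg.n_genes // 4)
        low = []
        all_genes = [int(g) for g in self.entrez]
        for _ in range(n_low):
            u, v = rng.choice(len(all_genes), size=2, replace=False)
            low.append(((all_genes[int(u)], all_genes[int(v)]), int(rng.integers(150, 700))))
        self.low_score_edges = low
        self.self_loop_gene = int(self.entrez[int(rng.integers(0, len(self.entrez)))])
        self.phantoms = [f"9606.PHANTOM{i:04d}" for i in range(5)]

    def _build_stats(self, rng: np.random.Generator) -> None:
        n = len(self.entrez)
        magma_p = rng.uniform(0.0, 1.0, size=n)
        z_pd = rng.normal(0.0, 1.0, size=n)
        z_bc = rng.normal(0.0, 1.0, size=n)
        idx = {int(g): i for i, g in enumerate(self.entrez)}
        survivors = self.anchors + self.extra_shared + self.negative_plants
        for g in survivors:
            magma_p[idx[g]] = 10.0 ** -float(rng.uniform(6, 10))
            s = 1.0 if rng.random() < 0.5 else -1.0
            z_pd[idx[g]] = s * float(rng.uniform(2, 5))
            z_bc[idx[g]] = s * float(rng.uniform(2, 5))
        for g in self.discordant:
            magma_p[idx[g]] = 10.0 ** -float(rng.uniform(6, 10))
            z_pd[idx[g]] = float(rng.uniform(2, 4))
            z_bc[idx[g]] = -float(rng.uniform(2, 4))
        if self.anchors:
            magma_p[idx[self.anchors[0]]] = 1e-8
            z_pd[idx[self.anchors[0]]] = 3.2
            z_bc[idx[self.anchors[0]]] = 2.1
        if self.discordant:
            z_pd[idx[self.discordant[0]]] = 2.0
            z_bc[idx[self.discordant[0]]] = -2.0
        self.magma_p = magma_p
        self.z_pd = z_pd
        self.z_bc = z_bc
        self.nsnps = rng.integers(5, 200, size=n)

    @property
    def shared_truth(self) -> list[int]:
        """Genes that should survive all three shared-gene filters."""
        return sorted(self.anchors + self.extra_shared)


@lru_cache(maxsize=8)
def _plan(cfg: SyntheticConfig) -> _Plan:
    return _Plan(cfg)


def _protein(entrez: int) -> str:
    return f"9606.ENSP{entrez:011d}"


def generate_network(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write STRING-format links and alias files.

    The links file contains sub-threshold edges, duplicate records, one
    self-loop and edges touching proteins with no Entrez alias, so the
    loader's filtering is exercised; the >= 700 subgraph equals the designed
    topology.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = _plan(cfg)
    links = outdir / "string_links.txt"
    with open(links, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for (u, v), score in zip(plan.design_edges, plan.edge_scores):
            fh.write(f"{_protein(u)} {_protein(v)} {int(score)}\n")
        for (u, v), score in plan.duplicate_edges:
            fh.write(f"{_protein(v)} {_protein(u)} {score}\n")
        for (u, v), score in plan.low_score_edges:
            fh.write(f"{_protein(u)} {_protein(v)} {score}\n")
        g = plan.self_loop_gene
        fh.write(f"{_protein(g)} {_protein(g)} 950\n")
        for i, p in enumerate(plan.phantoms):
            fh.write(f"{p} {plan.phantoms[(i + 1) % len(plan.phantoms)]} 900\n")
    aliases = outdir / "string_aliases.tsv"
    unmapped = set(plan.unmapped)
    with open(aliases, "w") as fh:
        fh.write("#string_protein_id\talias\tsource\n")
        for g in plan.entrez:
            g = int(g)
            if g not in unmapped:
                fh.write(f"{_protein(g)}\t{g}\tEntrez_Gene\n")
            fh.write(f"{_protein(g)}\tG{g}\tBLAST_KEGG_NAME\n")
    return {"links": links, "aliases": aliases}


def generate_gene_annotations(cfg: SyntheticConfig, outdir) -> Path:
    """Write the gene position table (entrez, chrom, start, end; 1-based)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "gene_annotations.tsv"
    _plan(cfg).ann.to_csv(path, sep="\t", index=False)
    return path


def generate_pathways(cfg: SyntheticConfig, outdir) -> Path:
    """Write the GMT pathway file (planted modules plus random sets)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = _plan(cfg)
    path = outdir / "pathways.gmt"
    with open(path, "w") as fh:
        for name in sorted(plan.pathways):
            members = "\t".join(str(g) for g in plan.pathways[name])
            fh.write(f"{name}\tsynthetic\t{members}\n")
    return path


def generate_disease_pair_artifacts(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write the correlated-loci, gene-association and signed-z tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = _plan(cfg)
    loci_path = outdir / "loci.tsv"
    loci = plan.loci.copy()
    loci["sign"] = np.where(loci["sign"] > 0, "+", "-")
    loci.to_csv(loci_path, sep="\t", index=False)

    magma_path = outdir / "magma_genes.tsv"
    zstat = sps.norm.isf(np.clip(plan.magma_p, 1e-300, 1.0))
    magma = pd.DataFrame(
        {
            "GENE": plan.entrez,
            "CHR": plan.ann["chrom"].to_numpy(),
            "START": plan.ann["start"].to_numpy(),
            "STOP": plan.ann["end"].to_numpy(),
            "NSNPS": plan.nsnps,
            "ZSTAT": np.round(zstat, 4),
            "P": plan.magma_p,
        }
    )
    with open(magma_path, "w") as fh:
        fh.write("GENE CHR START STOP NSNPS ZSTAT P\n")
        for row in magma.itertuples(index=False):
            fh.write(
                f"{row.GENE} {row.CHR} {row.START} {row.STOP} {row.NSNPS} "
                f"{row.ZSTAT:.4f} {row.P:.6g}\n"
            )

    sm_path = outdir / "smultixcan.tsv"
    sm = pd.DataFrame(
        {
            "gene": plan.entrez,
            "z_pd": np.round(plan.z_pd, 4),
            "z_bc": np.round(plan.z_bc, 4),
        }
    )
    sm.to_csv(sm_path, sep="\t", index=False, float_format="%.4f")
    return {"loci": loci_path, "magma": magma_path, "smultixcan": sm_path}


def generate_drug_tables(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write the drug-target table and the breast-cancer drug list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = _plan(cfg)
    drug_path = outdir / "drug_targets.tsv"
    with open(drug_path, "w") as fh:
        fh.write("drug_id\tname\tindication\ttargets\n")
        for d in plan.drugs:
            fh.write(
                f"{d['drug_id']}\t{d['name']}\t{d['indication']}\t"
                + ";".join(str(t) for t in d["targets"])
                + "\n"
            )
    bc_path = outdir / "bc_drugs.tsv"
    with open(bc_path, "w") as fh:
        fh.write("drug_id\tstatus\n")
        for i, d in enumerate(sorted(plan.bc_drugs)):
            fh.write(f"{d}\t{'approved' if i % 2 == 0 else 'trial'}\n")
    return {"drugs": drug_path, "bc_drugs": bc_path}


def generate_all(cfg: SyntheticConfig, outdir) -> dict:
    """Generate every input file plus a ground-truth JSON; returns the paths."""
    outdir = Path(outdir)
    paths: dict = {}
    paths.update(generate_network(cfg, outdir))
    paths["annotations"] = generate_gene_annotations(cfg, outdir)
    paths["gmt"] = generate_pathways(cfg, outdir)
    paths.update(generate_disease_pair_artifacts(cfg, outdir))
    paths.update(generate_drug_tables(cfg, outdir))
    plan = _plan(cfg)
    truth = {
        "anchors": plan.anchors,
        "extra_shared": plan.extra_shared,
        "shared_genes": plan.shared_truth,
        "discordant": plan.discordant,
        "negative_locus_plants": plan.negative_plants,
        "boundary_in": plan.boundary_in,
        "boundary_out": plan.boundary_out,
        "planted_pathways": [n for n in plan.pathways if n.startswith("PLANTED_")],
        "modules": {f"PLANTED_MODULE_{k:03d}": mod for k, mod in enumerate(plan.modules)},
        "tp_drugs": plan.tp_drugs,
        "decoy_drugs": plan.decoy_drugs,
        "bc_drugs": plan.bc_drugs,
        "unmapped_genes": plan.unmapped,
        "self_loop_gene": plan.self_loop_gene,
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths
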