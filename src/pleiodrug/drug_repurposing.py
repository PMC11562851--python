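"""Candidate-drug assembly and enrichment evaluation.

A drug indicated for a predisposing disease becomes a repurposing candidate
when at least one of its targets is significantly linked (by the
degree-matched propagation test) to at least one shared canonical pathway of
that disease pair.  Each recommendation carries an evidence chain
drug -> target -> pathway -> supporting shared genes.  The candidate list is
evaluated against drugs already investigated or approved for breast cancer
with a one-sided Fisher's exact test; the reported odds ratio is the
conditional maximum-likelihood estimate (the value R's ``fisher.test``
prints), alongside the sample cross-product ratio.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pathways import PathwayCollection

logger = logging.getLogger("pleiodrug")

__all__ = [
    "DrugRecord",
    "read_drug_table",
    "read_bc_drugs",
    "shared_pathways",
    "candidate_drugs",
    "fisher_enrichment",
    "EnrichmentResult",
    "write_report",
]


@dataclass
class DrugRecord:
    drug_id: str
    name: str
    indication: str
    targets: frozenset[int]

    @property
    def n_targets(self) -> int:
        return len(self.targets)


def read_drug_table(path) -> list[DrugRecord]:
    """Drug-target TSV: drug_id, name, indication, targets (semicolon-separated
    Entrez IDs; may be empty).  Target lists are deduplicated per drug."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    required = {"drug_id", "name", "indication", "targets"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing column(s): {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        targets = frozenset(int(t) for t in str(row.targets).split(";") if t.strip())
        records.append(
            DrugRecord(
                drug_id=row.drug_id, name=row.name, indication=row.indication, targets=targets
            )
        )
    return records


def read_bc_drugs(path) -> set[str]:
    """Breast-cancer investigated/approved drug list (drug_id, status)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if "drug_id" not in df.columns:
        raise ValueError("breast-cancer drug list missing column: drug_id")
    return set(df["drug_id"])


def shared_pathways(
    gene_stage: pd.DataFrame, collection: PathwayCollection
) -> tuple[PathwayCollection, dict[str, set[int]]]:
    """Pathways significantly linked to at least one shared gene.

    Returns the sub-collection together with, per pathway, the set of
    supporting shared genes (the seeds it was significant for).
    """
    sig = gene_stage[gene_stage["significant"]]
    support: dict[str, set[int]] = {}
    for row in sig.itertuples(index=False):
        support.setdefault(row.pathway, set()).add(int(row.seed))
    return collection.subset(support.keys()), support


def candidate_drugs(
    drugs: list[DrugRecord],
    target_stage: pd.DataFrame,
    support: dict[str, set[int]],
    disease_pair: str = "pair",
) -> tuple[set[str], pd.DataFrame]:
    """Candidate set plus one evidence chain per significant
    (drug, target, pathway) triple.

    A drug with no network-mapped targets can never be a candidate but stays
    in the evaluation universe.  Chains are sorted by (drug, p_adj) for
    deterministic output.
    """
    sig = target_stage[target_stage["significant"]]
    by_target: dict[int, list] = {}
    for row in sig.itertuples(index=False):
        by_target.setdefault(int(row.seed), []).append(row)
    candidates: set[str] = set()
    chains = []
    for drug in drugs:
        for target in sorted(drug.targets):
            for row in by_target.get(target, ()):
                candidates.add(drug.drug_id)
                chains.append(
                    {
                        "drug_id": drug.drug_id,
                        "name": drug.name,
                        "indication": drug.indication,
                        "target": target,
                        "pathway": row.pathway,
                        "shared_genes": ";".join(map(str, sorted(support.get(row.pathway, ())))),
                        "p_perm": row.p_perm,
                        "p_adj": row.p_adj,
                        "disease_pair": disease_pair,
                    }
                )
    chain_df = pd.DataFrame(
        chains,
        columns=[
            "drug_id",
            "name",
            "indication",
            "target",
            "pathway",
            "shared_genes",
            "p_perm",
            "p_adj",
            "disease_pair",
        ],
    )
    if len(chain_df):
        chain_df = chain_df.sort_values(["drug_id", "p_adj", "target", "pathway"]).reset_index(
            drop=True
        )
    return candidates, chain_df


@dataclass
class EnrichmentResult:
    """2x2 evaluation of candidates against breast-cancer drugs.

    table rows: candidate / non-candidate; columns: BC drug / not.
    ``or_cmle`` is the conditional-MLE odds ratio (solves E_psi[a] = a under
    Fisher's noncentral hypergeometric likelihood with fixed margins);
    ``or_sample`` is the cross-product ratio ad/bc (inf when bc = 0).
    """

    table: np.ndarray
    p_one_sided: float
    or_cmle: float
    or_sample: float

    def as_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "p_one_sided": self.p_one_sided,
            "or_cmle": self.or_cmle,
            "or_sample": self.or_sample,
        }


def fisher_enrichment(
    candidates: set[str], universe: set[str], bc_drugs: set[str]
) -> EnrichmentResult:
    """One-sided Fisher's exact test for candidate / breast-cancer overlap.

    ``universe`` is every drug indicated for the predisposing diseases,
    including drugs whose targets never mapped to the network.  The one-sided
    p is the upper hypergeometric tail P(X >= a) given the table margins.
    """
    if not universe:
        raise ValueError("empty drug universe")
    if not candidates <= universe:
        raise ValueError("candidates must be a subset of the drug universe")
    bc = bc_drugs & universe
    a = len(candidates & bc)
    b = len(candidates - bc)
    c = len(bc - candidates)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    p = float(stats.fisher_exact(table, alternative="greater").pvalue)
    or_sample = float(a * d) / (b * c) if b * c > 0 else float("inf")
    or_cmle = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    return EnrichmentResult(table=table, p_one_sided=p, or_cmle=or_cmle, or_sample=or_sample)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def write_report(
    outdir,
    candidates: set[str],
    chains: pd.DataFrame,
    enrichment: EnrichmentResult | None,
    metadata: dict | None = None,
    input_paths: dict | None = None,
) -> None:
    """Write candidate and chain TSVs plus an enrichment/metadata JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(chains):
        counts = chains.groupby("drug_id").size()
        cand_df = pd.DataFrame(
            {
                "drug_id": sorted(candidates),
                "indication": [
                    chains.loc[chains["drug_id"] == d, "indication"].iloc[0]
                    for d in sorted(candidates)
                ],
                "n_chains": [int(counts.get(d, 0)) for d in sorted(candidates)],
            }
        )
    else:
        cand_df = pd.DataFrame(columns=["drug_id", "indication", "n_chains"])
    cand_df.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    chains.to_csv(outdir / "evidence_chains.tsv", sep="\t", index=False)
    payload = {
        "enrichment": enrichment.as_dict() if enrichment is not None else None,
        "n_candidates": len(candidates),
        "metadata": metadata or {},
    }
    if input_paths:
        payload["input_digests"] = {k: _digest(v) for k, v in sorted(input_paths.items())}
    with open(outdir / "enrichment.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
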