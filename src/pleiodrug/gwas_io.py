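"""GWAS-derived inputs: summary-statistics QC, correlated-region tables,
positional gene mapping, and the shared-gene filters.

A "shared gene" for a disease pair is a protein-coding gene that

1. lies within (or within ``window_bp`` = 10 kb of) a genomic locus whose
   SNP effects are *positively* correlated between the two diseases,
2. is significantly associated with the predisposing disease by a
   gene-based test (Benjamini-Hochberg adjusted p < 0.05), and
3. is predicted to be dysregulated in the *same direction* in both
   diseases (sign concordance of the per-disease signed z statistics).

All coordinates are 1-based with inclusive interval ends; interval overlap
means at least one shared base, so a gap of exactly ``window_bp`` still maps
while ``window_bp`` + 1 does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("pleiodrug")

__all__ = [
    "qc_summary_stats",
    "read_regions",
    "read_gene_annotations",
    "map_regions_to_genes",
    "read_magma",
    "read_smultixcan",
    "build_gene_stats",
    "filter_shared_genes",
    "SharedGeneSet",
    "bh_adjust",
]

_SUMSTATS_REQUIRED = ["rsid", "chrom", "pos", "effect_allele", "alt_allele", "beta", "pvalue"]
_AUTOSOMES = {str(c) for c in range(1, 23)}


def _parse_chrom(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.removeprefix("chr")
    return s


def qc_summary_stats(
    records: pd.DataFrame,
    reference: pd.DataFrame,
    info_threshold: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """Clean a GWAS summary-statistics table against a reference allele panel.

    ``records`` needs columns rsid, chrom, pos, effect_allele, alt_allele,
    beta, pvalue and optionally info.  ``reference`` maps rsid -> (REF, ALT)
    (columns ``rsid``, ``ref``, ``alt``).  Removal classes, counted in the
    returned report:

    - ``duplicate_rsid``: rsID appearing more than once (all copies dropped);
    - ``non_autosomal``: chromosome outside 1-22;
    - ``non_biallelic``: identical alleles or comma-separated multi-alleles;
    - ``low_info``: info below ``info_threshold`` (only when the column exists,
      as imputation scores are only available for some studies);
    - ``unharmonizable``: rsID absent from the reference, or alleles matching
      neither reference orientation.

    Records whose effect allele equals the reference ALT are kept as-is;
    records whose effect allele equals the reference REF have the beta sign
    flipped and alleles swapped.  Re-applying the function is a no-op.
    """
    missing = [c for c in _SUMSTATS_REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"summary statistics missing required column(s): {missing}")
    for col in ("rsid", "ref", "alt"):
        if col not in reference.columns:
            raise ValueError(f"reference allele table missing column: {col}")

    report = {"n_input": len(records)}
    df = records.copy()

    dup = df["rsid"].duplicated(keep=False)
    report["duplicate_rsid"] = int(dup.sum())
    df = df[~dup]

    chrom = _parse_chrom(df["chrom"])
    autosomal = chrom.isin(_AUTOSOMES)
    report["non_autosomal"] = int((~autosomal).sum())
    df = df[autosomal]
    df["chrom"] = _parse_chrom(df["chrom"]).astype(int)

    ea = df["effect_allele"].astype(str).str.upper()
    aa = df["alt_allele"].astype(str).str.upper()
    biallelic = (ea != aa) & ~ea.str.contains(",") & ~aa.str.contains(",")
    report["non_biallelic"] = int((~biallelic).sum())
    df = df[biallelic]

    if "info" in df.columns:
        info_ok = df["info"].astype(float) >= info_threshold
        report["low_info"] = int((~info_ok).sum())
        df = df[info_ok]
    else:
        report["low_info"] = 0

    ref_map = reference.set_index("rsid")
    in_ref = df["rsid"].isin(ref_map.index)
    n_unharm = int((~in_ref).sum())
    df = df[in_ref]
    if len(df):
        ref = ref_map.loc[df["rsid"], "ref"].astype(str).str.upper().to_numpy()
        alt = ref_map.loc[df["rsid"], "alt"].astype(str).str.upper().to_numpy()
        ea = df["effect_allele"].astype(str).str.upper().to_numpy()
        aa = df["alt_allele"].astype(str).str.upper().to_numpy()
        as_is = (ea == alt) & (aa == ref)
        flip = (ea == ref) & (aa == alt)
        n_unharm += int((~(as_is | flip)).sum())
        df = df.copy()
        df["effect_allele"] = np.where(flip, alt, ea)
        df["alt_allele"] = np.where(flip, ref, aa)
        df["beta"] = np.where(flip, -df["beta"].astype(float), df["beta"].astype(float))
        df = df[as_is | flip]
    report["unharmonizable"] = n_unharm
    report["n_output"] = len(df)
    if len(df) == 0:
        logger.warning("summary-statistics QC produced an empty table")
    return df.reset_index(drop=True), report


def read_regions(path, disease_pair: str | None = None) -> pd.DataFrame:
    """Read a correlated-region table (chrom, start, end, sign, qvalue[, pair]).

    The sign column may be '+', '-', '+1', '-1', 1 or -1; it is normalised to
    integers +1/-1.  A row with start > end is a fatal error reported with
    its line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "sign", "qvalue", "disease_pair"])
    required = {"chrom", "start", "end", "sign", "qvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing column(s): {sorted(missing)}")
    bad = df["start"] > df["end"]
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(f"malformed interval (start > end) at line {lineno}")
    sign = df["sign"].astype(str).str.strip().map(
        {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}
    )
    if sign.isna().any():
        raise ValueError("unrecognised sign value in region table")
    df = df.copy()
    df["sign"] = sign.astype(int)
    df["chrom"] = _parse_chrom(df["chrom"]).astype(int)
    if "disease_pair" not in df.columns:
        df["disease_pair"] = disease_pair if disease_pair is not None else "pair"
    return df


def read_gene_annotations(path) -> pd.DataFrame:
    """Gene position table: entrez, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=0)
    required = {"entrez", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation table missing column(s): {sorted(missing)}")
    return df


def map_regions_to_genes(
    regions: pd.DataFrame,
    annotations: pd.DataFrame,
    window_bp: int = 10_000,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Map correlated regions to genes within ±``window_bp``.

    A gene maps to a region when [start - window, end + window] of the gene
    overlaps the region interval (inclusive ends: a gap of exactly
    ``window_bp`` still maps).  With ``positive_only`` only regions with
    sign +1 are used.  Returns one row per gene (deduplicated across
    regions, keeping the first matching region for provenance).
    """
    use = regions[regions["sign"] == 1] if positive_only else regions
    ann = annotations.copy()
    chrom_ok = _parse_chrom(ann["chrom"]).isin(_AUTOSOMES)
    if (~chrom_ok).any():
        logger.warning(
            "skipping %d gene(s) with unknown chromosome", int((~chrom_ok).sum())
        )
        ann = ann[chrom_ok]
    ann["chrom"] = _parse_chrom(ann["chrom"]).astype(int)

    rows = []
    for region in use.itertuples(index=False):
        on_chrom = ann[ann["chrom"] == region.chrom]
        hit = on_chrom[
            (on_chrom["start"] - window_bp <= region.end)
            & (on_chrom["end"] + window_bp >= region.start)
        ]
        for g in hit.itertuples(index=False):
            rows.append(
                {
                    "entrez": int(g.entrez),
                    "chrom": int(g.chrom),
                    "gene_start": int(g.start),
                    "gene_end": int(g.end),
                    "locus_start": int(region.start),
                    "locus_end": int(region.end),
                    "locus_sign": int(region.sign),
                    "locus_qvalue": float(region.qvalue),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "entrez",
                "chrom",
                "gene_start",
                "gene_end",
                "locus_start",
                "locus_end",
                "locus_sign",
                "locus_qvalue",
            ]
        )
    out = pd.DataFrame(rows).drop_duplicates(subset="entrez", keep="first")
    return out.reset_index(drop=True)


def read_magma(path) -> pd.DataFrame:
    """Read a MAGMA-style gene association table (whitespace-separated).

    Expects at least GENE and P columns; returns entrez, magma_p and the
    genome-wide BH-adjusted magma_p_bh over all genes in the file.
    """
    df = pd.read_csv(path, sep=r"\s+", header=0)
    if "GENE" not in df.columns or "P" not in df.columns:
        raise ValueError("MAGMA table must contain GENE and P columns")
    out = pd.DataFrame({"entrez": df["GENE"].astype(int), "magma_p": df["P"].astype(float)})
    out["magma_p_bh"] = bh_adjust(out["magma_p"].to_numpy())
    return out


def read_smultixcan(path) -> pd.DataFrame:
    """Read signed gene-regulation z statistics (gene, z_pd, z_bc)."""
    df = pd.read_csv(path, sep="\t", header=0)
    required = {"gene", "z_pd", "z_bc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signed z table missing column(s): {sorted(missing)}")
    return pd.DataFrame(
        {
            "entrez": df["gene"].astype(int),
            "z_pd": df["z_pd"].astype(float),
            "z_bc": df["z_bc"].astype(float),
        }
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def build_gene_stats(magma: pd.DataFrame, smultixcan: pd.DataFrame) -> pd.DataFrame:
    """Outer-join the gene association and signed-regulation tables."""
    return magma.merge(smultixcan, on="entrez", how="outer")


@dataclass
class SharedGeneSet:
    """Genes surviving the positional, association and concordance filters."""

    disease_pair: str
    genes: set[int]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.genes)

    def write(self, path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)


def filter_shared_genes(
    candidates: pd.DataFrame,
    gene_stats: pd.DataFrame,
    alpha: float = 0.05,
    disease_pair: str = "pair",
) -> SharedGeneSet:
    """Keep locus genes with adjusted gene-association p < alpha and
    direction-concordant signed z in both diseases.

    A z of exactly 0 carries no direction and counts as discordant.  Genes
    missing either statistic are dropped with a logged reason.
    """
    if candidates.empty:
        return SharedGeneSet(disease_pair=disease_pair, genes=set(), provenance=candidates)
    merged = candidates.merge(gene_stats, on="entrez", how="left")
    missing = merged["magma_p_bh"].isna() | merged["z_pd"].isna() | merged["z_bc"].isna()
    if missing.any():
        logger.info(
            "dropping %d locus gene(s) missing association or direction statistics",
            int(missing.sum()),
        )
    merged = merged[~missing]
    sig = merged["magma_p_bh"] < alpha
    concordant = np.sign(merged["z_pd"]) == np.sign(merged["z_bc"])
    concordant &= np.sign(merged["z_pd"]) != 0
    kept = merged[sig & concordant].reset_index(drop=True)
    return SharedGeneSet(
        disease_pair=disease_pair,
        genes=set(kept["entrez"].astype(int)),
        provenance=kept,
    )
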