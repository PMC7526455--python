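"""Local and distal regulatory target-gene prediction.

A SNP-gene pair is *local* when the SNP sits inside a promoter window of the
gene (1 kb around a TSS by default) and *distal* otherwise. A pair is
predicted as regulatory when the SNP is functional, the pair carries a
significant cis-QTL association validated by at least two datasets, a
colocalization posterior PP4 > 0.8 supports a shared causal variant for the
gene in at least one GWAS x QTL combination, and - for distal pairs only -
chromatin-interaction evidence links the SNP to the gene promoter in at least
two datasets. Genes are then labelled local when every predicted pair is
local, else distal; genes reached only by distal SNPs are flagged as
exclusively distal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, adjust_pvalues

logger = logging.getLogger(__name__)


@dataclass
class SnpGenePair:
    snp_id: str
    gene_id: str
    pair_class: str  # local | distal
    qtl_dataset_count: int
    interaction_dataset_count: int
    coloc_pp4_max: float
    predicted: bool


def filter_cis_qtl(
    assocs: pd.DataFrame,
    gene_models: dict[str, GeneModel] | None = None,
    fdr_max: float = 0.05,
    min_datasets: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep FDR-significant cis-QTL rows and count supporting datasets per pair.

    Expected columns: snp_id, gene_id, dataset_id, p and/or fdr (missing fdr
    is recomputed per dataset by Benjamini-Hochberg). Genes absent from the
    gene model are dropped and logged. Returns (significant rows, per-pair
    table with a ``validated`` flag for >= min_datasets distinct datasets).
    """
    df = assocs.copy()
    if gene_models is not None:
        known = df["gene_id"].isin(gene_models)
        if (~known).any():
            logger.warning(
                "%d cis-QTL rows reference genes without a TSS; dropped",
                int((~known).sum()),
            )
        df = df[known].copy()
    if "fdr" not in df.columns or df["fdr"].isna().all():
        df["fdr"] = np.nan
    missing = df["fdr"].isna()
    if missing.any():
        for dataset, idx in df[missing].groupby("dataset_id").groups.items():
            df.loc[idx, "fdr"] = adjust_pvalues(df.loc[idx, "p"].to_numpy(), "bh")
    sig = df[df["fdr"] < fdr_max].copy()
    counts = (
        sig.groupby(["snp_id", "gene_id"])["dataset_id"]
        .nunique()
        .rename("qtl_dataset_count")
        .reset_index()
    )
    counts["validated"] = counts["qtl_dataset_count"] >= min_datasets
    return sig, counts


def _interval_hits(
    ivs: list[GenomicInterval], chrom: str, start: int, end: int
) -> bool:
    return any(iv.chrom == chrom and iv.start < end and start < iv.end for iv in ivs)


def interaction_support(
    snp_chrom: str,
    snp_pos: int,
    gene_id: str,
    contacts: pd.DataFrame,
    promoters_by_gene: dict[str, list[GenomicInterval]],
) -> int:
    """Number of distinct contact datasets linking the SNP to the gene promoter.

    A contact supports the pair when the SNP (1-based position) falls in one
    anchor and any promoter window of the gene overlaps the other anchor, in
    either orientation. Trans-chromosomal pairs never count.
    """
    windows = promoters_by_gene.get(gene_id, [])
    if not windows:
        return 0
    p0 = snp_pos - 1
    datasets = set()
    for row in contacts.itertuples(index=False):
        snp_in_1 = row.chrom1 == snp_chrom and row.start1 <= p0 < row.end1
        snp_in_2 = row.chrom2 == snp_chrom and row.start2 <= p0 < row.end2
        if not (snp_in_1 or snp_in_2):
            continue
        if snp_in_1 and _interval_hits(windows, row.chrom2, row.start2, row.end2):
            datasets.add(row.dataset_id)
        elif snp_in_2 and _interval_hits(windows, row.chrom1, row.start1, row.end1):
            datasets.add(row.dataset_id)
    return len(datasets)


def is_local_pair(
    snp_chrom: str,
    snp_pos: int,
    gene_id: str,
    promoters_by_gene: dict[str, list[GenomicInterval]],
) -> bool:
    return any(
        iv.chrom == snp_chrom and iv.contains_pos(snp_pos)
        for iv in promoters_by_gene.get(gene_id, [])
    )


def predict_target_genes(
    functional_snps: set[str],
    snp_positions: dict[str, tuple[str, int]],
    qtl_pair_counts: pd.DataFrame,
    contacts: pd.DataFrame,
    coloc_pp4_by_gene: dict[str, float],
    promoters_by_gene: dict[str, list[GenomicInterval]],
    pp4_min: float = 0.8,
    min_qtl_datasets: int = 2,
    min_interaction_datasets: int = 2,
) -> tuple[list[SnpGenePair], pd.DataFrame]:
    """Conjoin all evidence into predicted SNP-gene pairs and gene labels.

    ``coloc_pp4_by_gene`` carries the maximum PP4 over all tested GWAS x QTL
    dataset combinations per gene. Returns the evaluated pairs plus a
    gene-level table with columns gene_id / gene_class (local|distal) /
    exclusively_distal, restricted to predicted genes.
    """
    pairs: list[SnpGenePair] = []
    for row in qtl_pair_counts.itertuples(index=False):
        snp_id, gene_id = row.snp_id, row.gene_id
        if snp_id not in snp_positions:
            continue
        chrom, pos = snp_positions[snp_id]
        local = is_local_pair(chrom, pos, gene_id, promoters_by_gene)
        n_int = interaction_support(chrom, pos, gene_id, contacts, promoters_by_gene)
        pp4 = float(coloc_pp4_by_gene.get(gene_id, 0.0))
        predicted = (
            snp_id in functional_snps
            and row.qtl_dataset_count >= min_qtl_datasets
            and pp4 > pp4_min
            and (local or n_int >= min_interaction_datasets)
        )
        pairs.append(
            SnpGenePair(
                snp_id=snp_id,
                gene_id=gene_id,
                pair_class="local" if local else "distal",
                qtl_dataset_count=int(row.qtl_dataset_count),
                interaction_dataset_count=n_int,
                coloc_pp4_max=pp4,
                predicted=predicted,
            )
        )
    rows = []
    by_gene: dict[str, list[SnpGenePair]] = {}
    for pair in pairs:
        if pair.predicted:
            by_gene.setdefault(pair.gene_id, []).append(pair)
    for gene_id in sorted(by_gene):
        classes = {p.pair_class for p in by_gene[gene_id]}
        gene_class = "local" if classes == {"local"} else "distal"
        rows.append(
            {
                "gene_id": gene_id,
                "gene_class": gene_class,
                "exclusively_distal": classes == {"distal"},
            }
        )
    gene_table = pd.DataFrame(rows, columns=["gene_id", "gene_class", "exclusively_distal"])
    return pairs, gene_table
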