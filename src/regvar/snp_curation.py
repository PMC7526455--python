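"""Build the positive / background / negative SNP universe.

Trait-associated tag SNPs are expanded through linkage disequilibrium (r^2 >
0.8) into the positive set; all noncoding SNPs inside the merged 1 Mb
genome-wide-significant loci form the background; noncoding SNPs outside the
loci and the MHC with low LD (r^2 < 0.1) to every catalogued GWAS SNP form the
empirical negative set used to calibrate the scoring null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, SnpClass, SnpRecord

logger = logging.getLogger(__name__)

# hg19 extended MHC; the region is named but not delimited in most GWAS
# resources, so it stays configurable.
DEFAULT_MHC = GenomicInterval("chr6", 25_000_000, 35_000_000, label="MHC")


@dataclass(frozen=True)
class LdPair:
    snp_a: str
    snp_b: str
    r2: float
    distance_bp: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1] (got {self.r2})")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")


@dataclass
class LocusSet:
    loci: list[GenomicInterval] = field(default_factory=list)
    mhc_region: GenomicInterval = DEFAULT_MHC

    def contains(self, chrom: str, pos: int) -> bool:
        return any(
            iv.chrom == chrom and iv.contains_pos(pos) for iv in self.loci
        )


def compute_r2(haplotypes: np.ndarray) -> float:
    """Squared LD correlation from phased haplotypes of two biallelic SNPs.

    ``haplotypes`` is an (n_haplotypes, 2) 0/1 matrix. Returns NaN for a
    monomorphic SNP (r^2 undefined).
    """
    h = np.asarray(haplotypes)
    if h.ndim != 2 or h.shape[1] != 2 or h.shape[0] < 2:
        raise ValueError("need an (n>=2, 2) haplotype matrix")
    if not np.isin(h, (0, 1)).all():
        raise ValueError("haplotypes must be binary 0/1")
    p_a = h[:, 0].mean()
    p_b = h[:, 1].mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    p_ab = (h[:, 0] * h[:, 1]).mean()
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def expand_tags(
    tags: list[SnpRecord],
    snp_table: dict[str, SnpRecord],
    ld_pairs: list[LdPair] | pd.DataFrame,
    r2_min: float = 0.8,
    max_dist: int = 1_000_000,
) -> dict[str, SnpRecord]:
    """LD-expand tag SNPs into the positive set (r^2 strictly above r2_min).

    Disease labels propagate from every linked tag (union). Coding/splicing
    SNPs never enter the positive set. A tag missing from the LD table is
    retained alone and logged.
    """
    if isinstance(ld_pairs, pd.DataFrame):
        ld_pairs = [
            LdPair(r.snp_a, r.snp_b, float(r.r2), int(getattr(r, "distance_bp", 0)))
            for r in ld_pairs.itertuples(index=False)
        ]
    neighbours: dict[str, list[tuple[str, float]]] = {}
    for pair in ld_pairs:
        if pair.distance_bp > max_dist:
            continue
        neighbours.setdefault(pair.snp_a, []).append((pair.snp_b, pair.r2))
        neighbours.setdefault(pair.snp_b, []).append((pair.snp_a, pair.r2))

    positives: dict[str, SnpRecord] = {}

    def _add(snp_id: str, diseases: set) -> None:
        rec = snp_table.get(snp_id)
        if rec is None or rec.coding_flag:
            return
        if snp_id not in positives:
            positives[snp_id] = SnpRecord(
                snp_id=rec.snp_id,
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref_allele,
                alt_allele=rec.alt_allele,
                risk_allele=rec.risk_allele,
                diseases=set(rec.diseases),
                snp_class=SnpClass.POSITIVE,
                coding_flag=rec.coding_flag,
            )
        positives[snp_id].diseases |= diseases

    for tag in tags:
        if tag.coding_flag:
            continue
        _add(tag.snp_id, set(tag.diseases))
        linked = neighbours.get(tag.snp_id)
        if not linked:
            logger.info("tag %s absent from LD table; retained alone", tag.snp_id)
            continue
        for proxy_id, r2 in linked:
            if r2 > r2_min:
                _add(proxy_id, set(tag.diseases))
    return positives


def _merge_intervals(ivs: list[tuple[str, int, int]]) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in ivs:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, label="locus"))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e, label="locus"))
    return out


def _subtract(iv: GenomicInterval, cut: GenomicInterval) -> list[GenomicInterval]:
    if iv.chrom != cut.chrom or cut.end <= iv.start or cut.start >= iv.end:
        return [iv]
    pieces = []
    if iv.start < cut.start:
        pieces.append(GenomicInterval(iv.chrom, iv.start, cut.start, iv.label))
    if cut.end < iv.end:
        pieces.append(GenomicInterval(iv.chrom, cut.end, iv.end, iv.label))
    return pieces


def define_loci(
    tags: list[SnpRecord],
    flank: int = 1_000_000,
    mhc: GenomicInterval = DEFAULT_MHC,
) -> LocusSet:
    """Merged 1 Mb windows around tags, with any MHC intersection removed.

    Truncation may split a locus into two disjoint segments; a window fully
    inside the MHC is dropped.
    """
    if not tags:
        raise ValueError("define_loci needs at least one tag SNP")
    windows = [
        (t.chrom, max(0, t.pos - 1 - flank), t.pos - 1 + flank + 1) for t in tags
    ]
    merged = _merge_intervals(windows)
    loci: list[GenomicInterval] = []
    for iv in merged:
        loci.extend(_subtract(iv, mhc))
    return LocusSet(loci=loci, mhc_region=mhc)


def classify_snps(
    all_snps: dict[str, SnpRecord],
    loci: LocusSet,
    positives: dict[str, SnpRecord],
    max_catalog_r2: dict[str, float] | None = None,
    catalog_r2_max: float = 0.1,
) -> dict[str, SnpClass]:
    """Assign exactly one class per SNP with precedence positive > background > negative.

    ``max_catalog_r2`` maps snp_id to its maximum r^2 with any GWAS-catalog
    SNP; absence means 0. SNPs fitting no class (coding SNPs, or noncoding
    SNPs outside loci with catalog LD above threshold) are ``excluded``.
    """
    max_catalog_r2 = max_catalog_r2 or {}
    classes: dict[str, SnpClass] = {}
    mhc = loci.mhc_region
    for snp_id, rec in all_snps.items():
        if snp_id in positives and not rec.coding_flag:
            classes[snp_id] = SnpClass.POSITIVE
            continue
        if rec.coding_flag:
            classes[snp_id] = SnpClass.EXCLUDED
            continue
        inside_locus = loci.contains(rec.chrom, rec.pos)
        if inside_locus:
            classes[snp_id] = SnpClass.BACKGROUND
            continue
        in_mhc = rec.chrom == mhc.chrom and mhc.contains_pos(rec.pos)
        if not in_mhc and max_catalog_r2.get(snp_id, 0.0) < catalog_r2_max:
            classes[snp_id] = SnpClass.NEGATIVE
        else:
            classes[snp_id] = SnpClass.EXCLUDED
    n_excl = sum(1 for c in classes.values() if c is SnpClass.EXCLUDED)
    if n_excl:
        logger.info("%d SNPs excluded from all classes", n_excl)
    return classes
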