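"""Epigenetic feature enrichment and fold-enrichment-weighted functional scoring.

Each epigenetic feature is one annotation (chromatin state, histone mark, DHS
or TF-binding peak set) in one cell type. Features significantly enriched in
trait-associated (positive) SNPs over background SNPs (FC > 1, Bonferroni
p < alpha across *all* features jointly) are selected; each SNP then receives
one score per category,

    S = sum_j FC_j * B_j

where B_j indicates overlap with selected feature j and the fold enrichment
FC_j is the weight. Functional support is called per category when a positive
SNP's score strictly exceeds the nearest-rank 95th percentile of the scores of
all negative SNPs (the empirical null).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ContingencyTable,
    GenomicInterval,
    SnpRecord,
    association_test_2x2,
    fold_change,
    overlap_annotate,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("HMM15", "histone", "DHS", "TFBS")


@dataclass
class EpigeneticFeature:
    feature_id: str
    category: str
    cell_type: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown epigenetic category {self.category!r}")


@dataclass
class FeatureEnrichment:
    feature_id: str
    category: str
    table: ContingencyTable
    fc: float
    p: float
    p_adj: float
    selected: bool


@dataclass
class CategoryScore:
    snp_id: str
    category: str
    score: float
    null_threshold: float
    support: bool


def annotation_matrix(
    snps: list[SnpRecord], features: list[EpigeneticFeature]
) -> np.ndarray:
    """Boolean (n_snps, n_features) overlap matrix."""
    chroms = [s.chrom for s in snps]
    positions = [s.pos for s in snps]
    cols = [
        overlap_annotate(chroms, positions, feat.peaks) for feat in features
    ]
    if not cols:
        return np.zeros((len(snps), 0), dtype=bool)
    return np.column_stack(cols)


def enrich_features(
    positives: list[SnpRecord],
    background: list[SnpRecord],
    features: list[EpigeneticFeature],
    alpha: float = 0.05,
) -> list[FeatureEnrichment]:
    """Chi-square enrichment of each feature in positives vs background.

    The Bonferroni denominator is the total feature count across all four
    categories, not the per-category count. Selection requires both FC > 1
    and adjusted p < alpha.
    """
    n_features = len(features)
    pos_mat = annotation_matrix(positives, features)
    bg_mat = annotation_matrix(background, features)
    out = []
    for j, feat in enumerate(features):
        if not feat.peaks:
            logger.warning("feature %s has zero peaks; skipped", feat.feature_id)
            out.append(
                FeatureEnrichment(
                    feat.feature_id,
                    feat.category,
                    ContingencyTable(0, len(positives), 0, len(background)),
                    fc=math.nan,
                    p=1.0,
                    p_adj=1.0,
                    selected=False,
                )
            )
            continue
        a = int(pos_mat[:, j].sum())
        c = int(bg_mat[:, j].sum())
        table = ContingencyTable(a, len(positives) - a, c, len(background) - c)
        res = association_test_2x2(table, method="chi2")
        fc = fold_change(a, len(positives), c, len(background))
        p_adj = min(1.0, res.p_value * n_features)
        selected = (not math.isnan(fc)) and fc > 1.0 and p_adj < alpha
        out.append(
            FeatureEnrichment(
                feat.feature_id, feat.category, table, fc, res.p_value, p_adj, selected
            )
        )
    return out


def score_category(snp_annotations: np.ndarray, weights: np.ndarray) -> float:
    """Accumulative fold-enrichment-weighted score S = sum_j FC_j * B_j."""
    b = np.asarray(snp_annotations)
    w = np.asarray(weights, dtype=float)
    if b.shape != w.shape:
        raise ValueError(
            f"annotation/weight length mismatch ({b.shape} vs {w.shape})"
        )
    return float(w[b.astype(bool)].sum())


def score_matrix(annotations: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized scores for an (n_snps, n_features) annotation matrix."""
    return annotations.astype(float) @ np.asarray(weights, dtype=float)


def nearest_rank_quantile(values: np.ndarray, quantile: float = 0.95) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic (no interpolation)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    k = max(1, math.ceil(quantile * v.size))
    return float(v[k - 1])


def null_support(
    positive_scores: np.ndarray,
    negative_scores: np.ndarray,
    quantile: float = 0.95,
) -> tuple[float, np.ndarray]:
    """Empirical-null support call for one epigenetic category.

    The threshold is the nearest-rank 95th percentile of the negative-SNP
    scores; support requires a strictly greater positive score (ties fail).
    """
    threshold = nearest_rank_quantile(negative_scores, quantile)
    flags = np.asarray(positive_scores, dtype=float) > threshold
    return threshold, flags


def epigenetic_support(scores: dict[str, CategoryScore]) -> set[str]:
    """Categories (0-4) in which a SNP has functional support."""
    return {cat for cat, cs in scores.items() if cs.support}
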