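"""Shared domain types, genomic-interval overlap, and exact 2x2 statistics.

Coordinate conventions used throughout the package: SNP positions are 1-based
(VCF convention); all intervals are 0-based half-open (BED convention). The
conversion between the two happens in exactly one place, :func:`overlap_annotate`,
so no other module needs to reason about off-by-one shifts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SnpClass",
    "SnpRecord",
    "GenomicInterval",
    "GeneModel",
    "ContingencyTable",
    "TestResult",
    "overlap_annotate",
    "promoter_windows",
    "association_test_2x2",
    "fisher_exact_pvalues",
    "fold_change",
    "adjust_pvalues",
]


class SnpClass(str, Enum):
    """Partition of the SNP universe used by the scoring stages."""

    TAG = "tag"
    POSITIVE = "positive"
    BACKGROUND = "background"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


@dataclass
class SnpRecord:
    """A single variant with its disease labels and class assignment."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str = "A"
    alt_allele: str = "G"
    risk_allele: str | None = None
    diseases: set = field(default_factory=set)
    snp_class: SnpClass | None = None
    coding_flag: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1 (got {self.pos})")
        if self.risk_allele is not None and self.risk_allele not in (
            self.ref_allele,
            self.alt_allele,
        ):
            raise ValueError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} is neither "
                f"ref {self.ref_allele!r} nor alt {self.alt_allele!r}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos: int) -> bool:
        """True if the 1-based position ``pos`` falls inside the interval."""
        return self.start <= pos - 1 < self.end


@dataclass
class GeneModel:
    """A gene with one or more transcript TSSs (1-based)."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str = "+"
    tss_list: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tss_list:
            raise ValueError(f"{self.gene_id}: tss_list must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (annotated, unannotated) x (group1, group2)."""

    a: int  # annotated, group 1
    b: int  # unannotated, group 1
    c: int  # annotated, group 2
    d: int  # unannotated, group 2

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins_positive(self) -> bool:
        return (
            self.a + self.b > 0
            and self.c + self.d > 0
            and self.a + self.c > 0
            and self.b + self.d > 0
        )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    p_adjusted: float | None = None
    fold_change: float | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# interval overlap


def _build_event_index(
    intervals: Iterable[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index = {}
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(pairs, dtype=np.int64)
        index[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
    return index


def overlap_annotate(
    chroms: Sequence[str],
    positions: Sequence[int],
    intervals: Iterable[GenomicInterval],
) -> np.ndarray:
    """Mark each 1-based SNP position that falls inside any interval.

    A SNP at 1-based position p is annotated iff p-1 lies in some [start, end).
    A chromosome naming mismatch between the two inputs yields an all-False
    column for the affected SNPs and a logged warning, never an exception.
    """
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    if chroms.shape != positions.shape:
        raise ValueError("chroms and positions must have equal length")
    index = _build_event_index(intervals)
    out = np.zeros(len(positions), dtype=bool)
    if index and len(chroms) and not (set(chroms) & set(index)):
        logger.warning(
            "no chromosome shared between SNPs (%s) and intervals (%s); "
            "all overlaps empty",
            sorted(set(chroms))[:3],
            sorted(index)[:3],
        )
    for chrom, (starts, ends) in index.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        p0 = positions[mask] - 1
        # covered iff #(starts <= p0) - #(ends <= p0) >= 1
        n_open = np.searchsorted(starts, p0, side="right")
        n_closed = np.searchsorted(ends, p0, side="right")
        out[mask] = (n_open - n_closed) >= 1
    return out


def promoter_windows(
    genes: Iterable[GeneModel], half_width: int = 1000
) -> list[GenomicInterval]:
    """One promoter interval per transcript TSS, labelled with the gene id.

    The window spans TSS +/- half_width in 1-based coordinates, i.e.
    [TSS-1-half_width, TSS-1+half_width+1) in BED coordinates, clipped at 0.
    """
    if not 500 <= half_width <= 10_000:
        raise ValueError(f"half_width must be in [500, 10000] bp (got {half_width})")
    windows = []
    for gene in genes:
        for tss in gene.tss_list:
            start = max(0, tss - 1 - half_width)
            end = tss - 1 + half_width + 1
            windows.append(GenomicInterval(gene.chrom, start, end, label=gene.gene_id))
    return windows


# ---------------------------------------------------------------------------
# 2x2 statistics


def fold_change(
    annotated_pos: int, total_pos: int, annotated_bg: int, total_bg: int
) -> float:
    """Fold enrichment of annotation in group 1 over group 2.

    FC = annotated_pos * total_bg / (annotated_bg * total_pos). A zero
    annotated background count returns +inf (flagged by the caller).
    """
    if min(annotated_pos, total_pos, annotated_bg, total_bg) < 0:
        raise ValueError("fold_change counts must be non-negative")
    if total_pos <= 0 or total_bg <= 0:
        raise ValueError("totals must be positive")
    if annotated_bg == 0:
        return math.inf if annotated_pos > 0 else math.nan
    return (annotated_pos * total_bg) / (annotated_bg * total_pos)


def _fisher_weights_int(n: int, r1: int, c1: int) -> tuple[int, np.ndarray, list[int]]:
    """Exact integer hypergeometric weights over the support of cell `a`.

    Returns (lo, support array of a values, list of integer weights
    C(r1, a) * C(n - r1, c1 - a)); the total mass is C(n, c1).
    """
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    weights = [math.comb(r1, a) * math.comb(n - r1, c1 - a) for a in support]
    return lo, support, weights


def fisher_exact_pvalues(n: int, r1: int, c1: int) -> np.ndarray:
    """Two-sided Fisher p for every table with margins (r1, n-r1) x (c1, n-c1).

    Uses the point-probability rule: p(a) = sum of hypergeometric probabilities
    of all outcomes no more likely than a. Computed in exact integer arithmetic,
    so ties are resolved exactly; returns one p per value of cell `a` over its
    support (ascending).
    """
    _, _, weights = _fisher_weights_int(n, r1, c1)
    total = sum(weights)
    order = sorted(range(len(weights)), key=weights.__getitem__)
    sorted_w = [weights[i] for i in order]
    prefix = np.cumsum(sorted_w, dtype=object)
    # rank of the last sorted weight <= w for each observed a
    import bisect

    out = np.empty(len(weights), dtype=float)
    for i, w in enumerate(weights):
        k = bisect.bisect_right(sorted_w, w)
        out[i] = float(prefix[k - 1] / total)
    return out


_EXACT_FISHER_MAX_TOTAL = 2000


def _fisher_two_sided(table: ContingencyTable) -> float:
    n, r1, c1 = table.total, table.a + table.b, table.a + table.c
    if n <= _EXACT_FISHER_MAX_TOTAL:
        lo, _, _ = _fisher_weights_int(n, r1, c1)
        return fisher_exact_pvalues(n, r1, c1)[table.a - lo]
    # large-count fallback: log-space point-probability rule with a relative
    # tie tolerance of 1e-7 (same convention as R's fisher.test)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = _stats.hypergeom.logpmf(support, n, r1, c1)
    obs = logpmf[table.a - lo]
    keep = logpmf <= obs + 1e-7
    return float(min(1.0, np.exp(logpmf[keep]).sum()))


def _pearson_chi2(table: ContingencyTable) -> tuple[float, float]:
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(_stats.chi2.sf(stat, df=1))


def association_test_2x2(
    table: ContingencyTable,
    method: str = "chi2",
    with_fold_change: bool = False,
) -> TestResult:
    """Pearson chi-square (no continuity correction) or two-sided Fisher test.

    A chi-square request falls back to Fisher whenever any expected cell is
    below 5; the test actually applied is recorded in ``method``. Zero margins
    give the degenerate result (statistic 0, p 1).
    """
    if method not in ("chi2", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    fc = None
    if with_fold_change and table.a + table.b > 0 and table.c + table.d > 0:
        fc = fold_change(table.a, table.a + table.b, table.c, table.c + table.d)
    if not table.margins_positive():
        return TestResult(0.0, 1.0, method=method, fold_change=fc, degenerate=True)
    if method == "chi2":
        obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
        expected = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0) / obs.sum()
        if (expected < 5).any():
            method = "fisher"
        else:
            stat, p = _pearson_chi2(table)
            return TestResult(stat, p, method="chi2", fold_change=fc)
    p = _fisher_two_sided(table)
    if table.b * table.c > 0:
        odds = (table.a * table.d) / (table.b * table.c)
    else:
        odds = math.inf if table.a * table.d > 0 else math.nan
    return TestResult(odds, p, method="fisher", fold_change=fc)


def adjust_pvalues(p_list: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, p*m). ``bh``: Benjamini-Hochberg step-up with
    monotonicity enforcement (statsmodels implementation).
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")
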