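"""Allele-specific TF motif calls, molecular-QTL filtering, and the final
functional-SNP conjunction.

The motif scanner is a position-weight-matrix log-odds scanner whose p-values
are exact under the background model: per-position log-odds scores are
discretized to a fixed bin width and the full null score distribution is built
by dynamic programming (convolution over motif positions), so
Pr(score >= s) is computed without simulation. A variant is called
allele-specific for a TF when the best motif hit overlapping the SNP passes
the p-value threshold for exactly one allele (gain: alt passes, loss: ref
passes). Calls are retained when supported by at least two motif databases
and the TF gene is expressed in at least one configured immune cell type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, SnpRecord, adjust_pvalues

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class Pwm:
    """Position probability matrix for one TF from one motif database."""

    tf_name: str
    database: str
    matrix: np.ndarray  # (L, 4) rows over A,C,G,T
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifHit:
    offset: int  # 0-based window start in the scanned sequence
    strand: str  # '+' or '-'
    score: float  # log2 odds (discretized)
    p: float


@dataclass
class AllelicMotifCall:
    snp_id: str
    tf_name: str
    direction: str  # gain | loss
    supporting_databases: set = field(default_factory=set)
    expressed_tf: bool = True
    retained: bool = False


@dataclass
class MolecularQtl:
    snp_id: str
    peak: GenomicInterval
    assay: str  # bQTL | hQTL | caQTL | dsQTL
    cell_type: str
    dataset_id: str
    p: float
    fdr: float
    local: bool


@dataclass
class FunctionalSnpCall:
    snp_id: str
    epigenetic_categories: set
    allelic_evidence: set  # subset of {motif, bQTL, hQTL, caQTL, dsQTL}
    functional: bool


class PwmScanner:
    """Log-odds PWM scanner with exact DP p-values under the background.

    Scores are log2(p_ij / bg_j) summed over motif positions, discretized to
    ``bin_width`` (default 1e-3 bits) so that the null distribution is a finite
    integer-supported distribution computed exactly by convolution. The window
    score reported is the same discretized value, making p-values reproducible
    bit-for-bit for a given configuration.
    """

    def __init__(
        self,
        pwm: Pwm,
        background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
        bin_width: float = 1e-3,
    ):
        self.pwm = pwm
        self.background = np.asarray(background, dtype=float)
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        self.bin_width = bin_width
        probs = (pwm.matrix + pwm.pseudocount) / (1.0 + 4.0 * pwm.pseudocount)
        # keep zero-probability cells finite when the pseudocount is 0
        probs = np.maximum(probs, 1e-9)
        logodds = np.log2(probs / self.background)
        self.bins = np.rint(logodds / bin_width).astype(np.int64)  # (L, 4)
        self._build_null()

    def _build_null(self) -> None:
        min_sum = int(self.bins.min(axis=1).sum())
        max_sum = int(self.bins.max(axis=1).sum())
        dist = np.zeros(max_sum - min_sum + 1)
        # running distribution over (partial score - running minimum)
        cur = np.array([1.0])
        cur_min = 0
        for row in self.bins:
            row_min = int(row.min())
            row_max = int(row.max())
            new = np.zeros(cur.size + row_max - row_min)
            for j in range(4):
                shift = int(row[j]) - row_min
                new[shift : shift + cur.size] += self.background[j] * cur
            cur = new
            cur_min += row_min
        assert cur_min == min_sum and cur.size == dist.size
        dist[:] = cur
        # survival function: sf[i] = Pr(score_int >= min_sum + i)
        self._min_sum = min_sum
        self._max_sum = max_sum
        self._sf = np.cumsum(dist[::-1])[::-1]

    def pvalue_int(self, score_int: int) -> float:
        if score_int <= self._min_sum:
            return 1.0
        if score_int > self._max_sum:
            return 0.0
        return float(self._sf[score_int - self._min_sum])

    def window_score_int(self, window: str) -> int | None:
        """Discretized score of one window; None if the window contains N."""
        total = 0
        for i, base in enumerate(window):
            j = _BASE_INDEX.get(base)
            if j is None:
                return None
            total += int(self.bins[i, j])
        return total

    def best_hit(
        self, sequence: str, window_range: tuple[int, int] | None = None
    ) -> MotifHit | None:
        """Best-scoring hit over both strands (optionally restricted windows).

        ``window_range`` is an inclusive range of window start offsets on the
        forward sequence; a window on the reverse strand is attributed to the
        forward-coordinates start of the window it covers.
        """
        seq = sequence.upper()
        L = len(self.pwm)
        if len(seq) < L:
            return None
        lo, hi = 0, len(seq) - L
        if window_range is not None:
            lo, hi = max(lo, window_range[0]), min(hi, window_range[1])
        rc = seq.translate(_COMPLEMENT)[::-1]
        best: MotifHit | None = None
        for w in range(lo, hi + 1):
            fwd = self.window_score_int(seq[w : w + L])
            if fwd is not None and (best is None or fwd > best_int):
                best_int, best = fwd, MotifHit(w, "+", fwd * self.bin_width, 0.0)
            rstart = len(seq) - L - w  # window covering same forward positions
            rev = self.window_score_int(rc[rstart : rstart + L])
            if rev is not None and (best is None or rev > best_int):
                best_int, best = rev, MotifHit(w, "-", rev * self.bin_width, 0.0)
        if best is not None:
            best.p = self.pvalue_int(round(best.score / self.bin_width))
        return best


def scan_pwm(
    sequence: str,
    pwm: Pwm,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
    p_threshold: float = 1e-4,
) -> dict[str, MotifHit | None]:
    """Best hit per strand over the whole sequence (windows with N skipped)."""
    scanner = PwmScanner(pwm, background)
    seq = sequence.upper()
    L = len(pwm)
    out: dict[str, MotifHit | None] = {"+": None, "-": None}
    if len(seq) < L:
        return out
    rc = seq.translate(_COMPLEMENT)[::-1]
    for strand, s in (("+", seq), ("-", rc)):
        best_int = None
        best_off = 0
        for w in range(len(s) - L + 1):
            sc = scanner.window_score_int(s[w : w + L])
            if sc is not None and (best_int is None or sc > best_int):
                best_int, best_off = sc, w
        if best_int is not None:
            out[strand] = MotifHit(
                best_off,
                strand,
                best_int * scanner.bin_width,
                scanner.pvalue_int(best_int),
            )
    return out


def call_allelic_motifs(
    snp: SnpRecord,
    flank: str,
    pwms: list[Pwm],
    expressed_tfs: set[str] | None = None,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
    p_threshold: float = 1e-4,
    center: int | None = None,
    scanners: dict[int, PwmScanner] | None = None,
) -> list[AllelicMotifCall]:
    """Gain/loss allele-specific motif calls for one SNP.

    ``flank`` carries the reference allele at ``center`` (default: middle
    base). For each TF, only windows overlapping the SNP are considered; the
    call is allele-specific when exactly one allele's best hit passes
    ``p_threshold``. Calls from multiple databases of the same TF and
    direction are merged; retention requires >= 2 databases and an expressed
    TF. ``expressed_tfs`` of None bypasses the expression filter (warned).
    """
    if center is None:
        center = len(flank) // 2
    flank = flank.upper()
    if flank[center] != snp.ref_allele.upper():
        logger.warning(
            "flank of %s does not carry the reference allele at the SNP; skipped",
            snp.snp_id,
        )
        return []
    if expressed_tfs is None:
        logger.warning("no TF expression table; expression filter bypassed")
    else:
        expressed_tfs = {t.upper() for t in expressed_tfs}
    ref_seq = flank
    alt_seq = flank[:center] + snp.alt_allele.upper() + flank[center + 1 :]
    merged: dict[tuple[str, str], set[str]] = {}
    for pwm in pwms:
        L = len(pwm)
        if center < L - 1 or len(flank) - center - 1 < L - 1:
            logger.warning(
                "flank of %s shorter than motif %s requires; skipped",
                snp.snp_id,
                pwm.tf_name,
            )
            continue
        if scanners is not None and id(pwm) in scanners:
            scanner = scanners[id(pwm)]
        else:
            scanner = PwmScanner(pwm, background)
            if scanners is not None:
                scanners[id(pwm)] = scanner
        window_range = (center - L + 1, center)
        ref_hit = scanner.best_hit(ref_seq, window_range)
        alt_hit = scanner.best_hit(alt_seq, window_range)
        ref_pass = ref_hit is not None and ref_hit.p < p_threshold
        alt_pass = alt_hit is not None and alt_hit.p < p_threshold
        if ref_pass == alt_pass:
            continue
        direction = "gain" if alt_pass else "loss"
        merged.setdefault((pwm.tf_name.upper(), direction), set()).add(pwm.database)
    calls = []
    for (tf, direction), dbs in sorted(merged.items()):
        expressed = expressed_tfs is None or tf in expressed_tfs
        calls.append(
            AllelicMotifCall(
                snp_id=snp.snp_id,
                tf_name=tf,
                direction=direction,
                supporting_databases=dbs,
                expressed_tf=expressed,
                retained=len(dbs) >= 2 and expressed,
            )
        )
    return calls


def filter_molecular_qtl(
    qtl_table: pd.DataFrame, fdr_max: float = 0.1
) -> tuple[pd.DataFrame, int]:
    """Keep local (SNP inside peak) molecular-QTL rows passing FDR < fdr_max.

    Expected columns: snp_id, chrom, pos, assay, cell_type, dataset_id,
    peak_chrom, peak_start, peak_end, p, and optionally fdr. A missing fdr
    column is recomputed per dataset by Benjamini-Hochberg. Rows with missing
    peak coordinates are dropped and counted.
    """
    df = qtl_table.copy()
    bad = df[["peak_chrom", "peak_start", "peak_end"]].isna().any(axis=1)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("%d molecular-QTL rows lack peak coordinates; dropped", n_dropped)
    df = df[~bad].copy()
    if "fdr" not in df.columns or df["fdr"].isna().all():
        df["fdr"] = np.nan
    missing = df["fdr"].isna()
    if missing.any():
        for dataset, idx in df[missing].groupby("dataset_id").groups.items():
            df.loc[idx, "fdr"] = adjust_pvalues(df.loc[idx, "p"].to_numpy(), "bh")
    df["local"] = (
        (df["peak_chrom"] == df["chrom"])
        & (df["peak_start"] <= df["pos"] - 1)
        & (df["pos"] - 1 < df["peak_end"])
    )
    kept = df[df["local"] & (df["fdr"] < fdr_max)].copy()
    return kept, n_dropped


def prioritize_functional_snps(
    snp_ids: list[str],
    epigenetic_support: dict[str, set],
    motif_calls: list[AllelicMotifCall],
    qtl_evidence: pd.DataFrame | None = None,
) -> list[FunctionalSnpCall]:
    """Functional = epigenetic support in >= 1 category AND >= 1 allelic evidence.

    Allelic evidence per SNP is the union of retained allele-specific motif
    calls and significant local molecular-QTL assays (bQTL/hQTL/caQTL/dsQTL).
    """
    motif_by_snp: dict[str, bool] = {}
    for call in motif_calls:
        if call.retained:
            motif_by_snp[call.snp_id] = True
    qtl_by_snp: dict[str, set] = {}
    if qtl_evidence is not None and len(qtl_evidence):
        for row in qtl_evidence.itertuples(index=False):
            qtl_by_snp.setdefault(row.snp_id, set()).add(row.assay)
    out = []
    for snp_id in snp_ids:
        categories = set(epigenetic_support.get(snp_id, set()))
        evidence: set = set(qtl_by_snp.get(snp_id, set()))
        if motif_by_snp.get(snp_id, False):
            evidence.add("motif")
        out.append(
            FunctionalSnpCall(
                snp_id=snp_id,
                epigenetic_categories=categories,
                allelic_evidence=evidence,
                functional=bool(categories) and bool(evidence),
            )
        )
    return out
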