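"""Bayesian colocalization of GWAS and molecular-QTL signals.

Two complementary routes are provided. The approximate-Bayes-factor (ABF)
route consumes full summary statistics: each SNP's Wakefield ABF is computed
from its effect estimate and standard error with a Normal prior on the true
effect (s.d. 0.15 for quantitative traits, 0.2 for case-control), and the five
hypothesis posteriors PP0-PP4 (no signal / GWAS only / QTL only / two distinct
causal variants / one shared causal variant) are assembled in log space with
per-SNP priors p1, p2, p12. The PICS route consumes only lead-SNP p-values
plus LD, builds per-SNP causal probabilities by fine-mapping, and weighs the
shared against the distinct causal configuration with the same priors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12
SD_PRIOR_QUANTITATIVE = 0.15
SD_PRIOR_CASE_CONTROL = 0.2


@dataclass
class ColocResult:
    locus_id: str
    gene_id: str
    dataset_pair: tuple[str, str]
    pp: np.ndarray  # PP0..PP4
    method: str  # abf | pics
    n_snps: int = 0

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("need exactly five posterior probabilities")
        if not math.isclose(self.pp.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"PP0-PP4 must sum to 1 (got {self.pp.sum()})")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def colocalized(self) -> bool:
        return self.pp4 > 0.8


@dataclass
class PicsSet:
    lead_snp: str
    probabilities: dict[str, float]
    credible_set: set = field(default_factory=set)


def _labf(
    beta: np.ndarray | None,
    se: np.ndarray | None,
    p: np.ndarray | None,
    n: np.ndarray | None,
    freq: np.ndarray | None,
    sd_prior: float,
    case_fraction: float | None = None,
) -> np.ndarray:
    """Log approximate Bayes factors per SNP.

    Prefers beta/se; falls back to z recovered from the two-sided p-value
    (signed by beta when present) with the sampling variance approximated
    from sample size and allele frequency.
    """
    if beta is not None and se is not None and np.all(np.asarray(se) > 0):
        z = np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)
        v = np.asarray(se, dtype=float) ** 2
    else:
        if p is None or n is None or freq is None:
            raise ValueError("need beta+se, or p with n and freq")
        z = _stats.norm.isf(np.asarray(p, dtype=float) / 2.0)
        if beta is not None:
            z = z * np.sign(np.where(beta == 0, 1.0, beta))
        f = np.asarray(freq, dtype=float)
        denom = 2.0 * np.asarray(n, dtype=float) * f * (1.0 - f)
        if case_fraction is not None:
            denom = denom * case_fraction * (1.0 - case_fraction)
        v = 1.0 / denom
    r = sd_prior**2 / (sd_prior**2 + v)
    return 0.5 * (np.log(1.0 - r) + r * z**2)


def _posteriors_from_labf(
    l1: np.ndarray,
    l2: np.ndarray,
    p1: float,
    p2: float,
    p12: float,
) -> np.ndarray:
    """Combine per-SNP log-ABFs of two traits into PP0-PP4 (log space)."""
    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = math.log(p1) + lsum1
    lh2 = math.log(p2) + lsum2
    # sum over i != j of exp(l1_i + l2_j)
    both = lsum1 + lsum2
    if both > lsum12:
        cross = both + math.log1p(-math.exp(lsum12 - both))
    else:  # all mass on the diagonal (e.g. a single shared SNP)
        cross = -math.inf
    lh3 = math.log(p1) + math.log(p2) + cross
    lh4 = math.log(p12) + lsum12
    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    return np.exp(lh - logsumexp(lh))


def coloc_abf(
    gwas: pd.DataFrame,
    qtl: pd.DataFrame,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    gwas_type: str = "cc",
    qtl_type: str = "quant",
    locus_id: str = "",
    gene_id: str = "",
    dataset_pair: tuple[str, str] = ("gwas", "qtl"),
) -> ColocResult:
    """ABF colocalization of two summary-statistic tables.

    Each table needs a ``snp_id`` column plus either ``beta`` and ``se`` or
    ``p`` with ``n`` and ``freq``. Only SNPs present in both tables are used;
    fewer than two shared SNPs is an error.
    """
    def _prep(df: pd.DataFrame, suffix: str) -> pd.DataFrame:
        out = df[["snp_id"]].copy()
        for name in ("beta", "se", "p", "n", "freq"):
            if name in df.columns:
                out[f"{name}{suffix}"] = df[name]
        return out

    merged = _prep(gwas, "_g").merge(_prep(qtl, "_q"), on="snp_id")
    if len(merged) < 2:
        raise ValueError(
            f"coloc needs >= 2 shared SNPs between GWAS and QTL "
            f"(got {len(merged)} for {locus_id}/{gene_id})"
        )

    def cols(suffix: str) -> dict:
        out = {}
        for name in ("beta", "se", "p", "n", "freq"):
            col = f"{name}{suffix}"
            out[name] = merged[col].to_numpy() if col in merged.columns else None
        return out

    g = cols("_g")
    q = cols("_q")
    sd_g = SD_PRIOR_CASE_CONTROL if gwas_type == "cc" else SD_PRIOR_QUANTITATIVE
    sd_q = SD_PRIOR_CASE_CONTROL if qtl_type == "cc" else SD_PRIOR_QUANTITATIVE
    l1 = _labf(g["beta"], g["se"], g["p"], g["n"], g["freq"], sd_g)
    l2 = _labf(q["beta"], q["se"], q["p"], q["n"], q["freq"], sd_q)
    pp = _posteriors_from_labf(l1, l2, p1, p2, p12)
    return ColocResult(locus_id, gene_id, dataset_pair, pp, "abf", len(merged))


def pics_probabilities(
    lead_snp: str,
    lead_neglog10p: float,
    ld_r: dict[str, float],
    exponent: float = 3.2,
    sd_scale: float = 0.5,
    credible_mass: float = 0.95,
) -> PicsSet:
    """Fine-mapping probabilities of causality given the lead significance.

    For each SNP with correlation r to the lead, the expected association
    strength is Normal with mean r^2 * S and s.d. sqrt(1-|r|^exponent) *
    sqrt(S) * sd_scale, where S is the lead SNP's -log10 p. The posterior is
    the normalized density of each SNP's expected distribution evaluated at S;
    the credible set is the smallest set reaching the cumulative mass.
    """
    if lead_neglog10p <= 0:
        raise ValueError("lead -log10 p must be positive")
    S = lead_neglog10p
    snps = list(ld_r)
    if lead_snp not in ld_r:
        snps = [lead_snp] + snps
    log_dens = {}
    degenerate = []
    for snp in snps:
        r = ld_r.get(snp, 1.0 if snp == lead_snp else 0.0)
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"LD r out of range for {snp}: {r}")
        sd = math.sqrt(max(0.0, 1.0 - abs(r) ** exponent)) * math.sqrt(S) * sd_scale
        if sd < 1e-12:  # perfect proxies of the lead: point mass
            degenerate.append(snp)
        else:
            log_dens[snp] = _stats.norm.logpdf(S, loc=r * r * S, scale=sd)
    probs: dict[str, float] = {}
    if degenerate:
        # perfect proxies dominate any finite density and share mass equally
        share = 1.0 / len(degenerate)
        probs = {snp: 0.0 for snp in log_dens}
        probs.update({snp: share for snp in degenerate})
    else:
        arr = np.array(list(log_dens.values()))
        norm = np.exp(arr - logsumexp(arr))
        probs = dict(zip(log_dens, norm))
    ordered = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
    credible: set = set()
    cum = 0.0
    for snp, pr in ordered:
        credible.add(snp)
        cum += pr
        if cum >= credible_mass:
            break
    return PicsSet(lead_snp=lead_snp, probabilities=probs, credible_set=credible)


def pics_coloc(
    gwas_set: PicsSet,
    qtl_set: PicsSet,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    locus_id: str = "",
    gene_id: str = "",
    dataset_pair: tuple[str, str] = ("gwas", "qtl"),
) -> ColocResult:
    """Colocalization from two fine-mapping probability vectors.

    The shared-causal mass is sum_i g_i q_i and the distinct-causal mass
    sum_{i != j} g_i q_j over the union SNP universe; they are weighed by the
    p12 and p1*p2 priors. PP0-PP2 are zero because PICS sets are only formed
    where both traits already carry a genome-wide-significant association.
    """
    universe = set(gwas_set.probabilities) | set(qtl_set.probabilities)
    g = np.array([gwas_set.probabilities.get(s, 0.0) for s in sorted(universe)])
    q = np.array([qtl_set.probabilities.get(s, 0.0) for s in sorted(universe)])
    shared = float((g * q).sum())
    distinct = float(g.sum() * q.sum() - shared)
    if not set(gwas_set.probabilities) & set(qtl_set.probabilities):
        logger.warning(
            "disjoint SNP sets for %s/%s: shared-causal posterior is 0",
            locus_id,
            gene_id,
        )
    m4 = p12 * shared
    m3 = p1 * p2 * distinct
    total = m4 + m3
    if total <= 0:
        pp = np.array([0.0, 0.0, 0.0, 1.0, 0.0])
    else:
        pp = np.array([0.0, 0.0, 0.0, m3 / total, m4 / total])
    return ColocResult(locus_id, gene_id, dataset_pair, pp, "pics", len(universe))
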