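"""Deterministic synthetic-data generator with a planted-truth manifest.

The generator emits every input family the pipeline consumes - SNP tables, an
LD table, epigenetic peak sets, motif libraries, flank sequences, molecular-
and cis-QTL tables, chromatin contacts, GWAS/QTL summary statistics, and the
gene-function / drug / PPI tables - on a small two-chromosome genome, with a
machine-readable manifest of every planted signal. Each output family draws
from its own labelled pseudo-random stream derived from the master seed, so
adding an output never perturbs the others, and a fixed seed reproduces the
bundle byte for byte.

The planted design is deliberately strong-signal: enriched epigenetic
features cover a designated positive subset at several times the background
rate, planted allele-specific motifs are near-consensus matches destroyed by
the alternative allele, true SNP-gene pairs carry two cis-QTL datasets, two
chromatin-contact datasets (distal pairs) and a shared-causal colocalization
scenario, while decoy pairs each lack exactly one evidence leg.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .allelic_evidence import BASES, Pwm

_STREAMS = (
    "snps",
    "ld",
    "features",
    "flanks",
    "molecular_qtl",
    "genes",
    "coloc",
    "function",
    "drugs",
)

DISEASES = ("rheumatoid_arthritis", "psoriasis", "ulcerative_colitis")
CATEGORIES = ("HMM15", "histone", "DHS", "TFBS")
CELL_TYPES = ("GM12878", "CD4_T", "monocyte", "B_cell", "NK_cell")


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS.index(label)])


@dataclass
class FixtureConfig:
    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_tags: int = 12
    proxies_per_tag: int = 4
    n_background: int = 1500
    n_negative: int = 3000
    n_enriched_per_category: int = 3
    n_null_per_category: int = 7
    target_fc: float = 6.0
    bg_coverage: float = 0.1
    n_functional: int = 24
    plant_genes: bool = True  # plant the 4-local / 8-distal gene design
    n_filler_genes: int = 8
    motif_length: int = 8
    flank_width: int = 25
    coloc_n: int = 5000
    coloc_effect: float = 0.5
    coloc_snps: int = 60

    @property
    def n_positive(self) -> int:
        return self.n_tags * (1 + self.proxies_per_tag)


@dataclass
class SyntheticTruth:
    enriched_features: list = field(default_factory=list)
    functional_snps: list = field(default_factory=list)
    snp_gene_pairs: list = field(default_factory=list)  # {snp, gene, class}
    local_genes: list = field(default_factory=list)
    distal_genes: list = field(default_factory=list)
    enriched_tfs: list = field(default_factory=list)
    drug_triples: list = field(default_factory=list)  # [candidate, disease, partners]
    class_counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _check_feasible(config: FixtureConfig) -> None:
    n_proxies = config.n_tags * config.proxies_per_tag
    if config.n_functional > n_proxies:
        raise ValueError(
            f"cannot plant {config.n_functional} functional SNPs with only "
            f"{n_proxies} proxies"
        )
    if config.plant_genes and (
        config.n_tags < 12 or config.proxies_per_tag < 3 or config.n_functional < 24
    ):
        raise ValueError(
            "the planted gene/drug design needs >= 12 tags, >= 3 proxies per "
            "tag and >= 24 functional SNPs"
        )
    cov = min(0.95, config.target_fc * config.bg_coverage)
    if config.n_functional > round(cov * config.n_positive) and config.n_functional:
        raise ValueError(
            "planted functional count exceeds the enriched-feature coverage "
            f"({config.n_functional} > {round(cov * config.n_positive)}); raise "
            "target_fc or bg_coverage"
        )


def _sample_positions(rng: np.random.Generator, lo: int, hi: int, n: int) -> np.ndarray:
    pos = rng.choice(np.arange(lo, hi), size=n, replace=False)
    return np.sort(pos)


def _random_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return BASES[i], BASES[j]


def _planted_pwms(config: FixtureConfig, rng: np.random.Generator) -> dict[str, Pwm]:
    """One near-consensus PWM per planted TF (single shared matrix per TF)."""
    pwms = {}
    for tf in ("TFA", "TFB", "TFC", "TFD", "TFE", "TFF"):
        cons = rng.integers(0, 4, size=config.motif_length)
        mat = np.zeros((config.motif_length, 4))
        mat[np.arange(config.motif_length), cons] = 1.0
        pwms[tf] = Pwm(tf, "planted", mat)
    return pwms


def generate_coloc_scenario(
    kind: str,
    n: int = 5000,
    effect: float = 0.5,
    snps: int = 60,
    seed: int | np.random.Generator = 0,
    block_size: int = 20,
    within_block_r: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary statistics for one locus under a causal configuration.

    ``kind`` is ``shared`` (one causal SNP common to GWAS and QTL),
    ``distinct`` (independent causal SNPs in uncorrelated LD blocks) or
    ``null`` (no association). Z-scores are drawn from a multivariate normal
    consistent with a block LD matrix; betas and s.e.s are reported on the
    standardized-genotype scale (se = 1/sqrt(n)).
    """
    if kind not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown scenario kind {kind!r}")
    if snps < 10:
        raise ValueError("need at least 10 SNPs per locus")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_blocks = math.ceil(snps / block_size)
    sigma = np.zeros((snps, snps))
    for b in range(n_blocks):
        lo, hi = b * block_size, min(snps, (b + 1) * block_size)
        sigma[lo:hi, lo:hi] = within_block_r
    np.fill_diagonal(sigma, 1.0)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = sigma + 1e-6 * np.eye(snps)
        chol = np.linalg.cholesky(sigma)
    z_causal = effect * math.sqrt(n)
    lam_g = np.zeros(snps)
    lam_q = np.zeros(snps)
    if kind in ("shared", "distinct"):
        causal_g = block_size // 2
        lam_g[causal_g] = z_causal
        causal_q = causal_g if kind == "shared" else min(snps - 1, 2 * block_size + block_size // 2)
        lam_q[causal_q] = z_causal
    z_g = sigma @ lam_g + chol @ rng.standard_normal(snps)
    z_q = sigma @ lam_q + chol @ rng.standard_normal(snps)
    se = 1.0 / math.sqrt(n)
    freq = rng.uniform(0.1, 0.5, size=snps)
    ids = [f"locus_snp_{i}" for i in range(snps)]
    gwas = pd.DataFrame(
        {"snp_id": ids, "beta": z_g * se, "se": se, "n": n, "freq": freq}
    )
    qtl = pd.DataFrame(
        {"snp_id": ids, "beta": z_q * se, "se": se, "n": n, "freq": freq}
    )
    return gwas, qtl


def generate_fixture(config: FixtureConfig, outdir: str | Path) -> SyntheticTruth:
    """Emit the full input bundle plus the planted-truth manifest."""
    _check_feasible(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "features").mkdir(exist_ok=True)
    truth = SyntheticTruth()
    chroms = sorted(config.chrom_lengths)

    # ---------------- SNP universe ----------------
    rng = _rng(config.seed, "snps")
    tags = []  # (snp_id, chrom, pos, disease)
    per_chrom = math.ceil(config.n_tags / len(chroms))
    t = 0
    for chrom in chroms:
        for pos in _sample_positions(rng, 2_000_000, 2_800_000, per_chrom):
            if t >= config.n_tags:
                break
            disease = DISEASES[t * len(DISEASES) // config.n_tags]
            tags.append((f"tag_{t}", chrom, int(pos), disease))
            t += 1
    proxies: dict[tuple[int, int], tuple[str, str, int]] = {}
    used = {(c, p) for _, c, p, _ in tags}
    for ti, (tag_id, chrom, pos, disease) in enumerate(tags):
        for k in range(config.proxies_per_tag):
            while True:
                off = int(rng.integers(1_000, 200_000)) * (1 if rng.random() < 0.5 else -1)
                if (chrom, pos + off) not in used:
                    break
            used.add((chrom, pos + off))
            proxies[(ti, k)] = (f"prox_{ti}_{k}", chrom, pos + off)

    # merged loci (windows +/- 1 Mb around tags) for background placement
    loci = {}
    for chrom in chroms:
        tp = [p for _, c, p, _ in tags if c == chrom]
        if tp:
            loci[chrom] = (max(1, min(tp) - 1_000_000), max(tp) + 1_000_000)
    background = []
    per_chrom_bg = math.ceil(config.n_background / len(loci))
    b = 0
    for chrom, (lo, hi) in loci.items():
        for pos in _sample_positions(rng, lo, hi, per_chrom_bg):
            if b >= config.n_background or (chrom, int(pos)) in used:
                continue
            used.add((chrom, int(pos)))
            background.append((f"bg_{b}", chrom, int(pos)))
            b += 1
    negatives = []
    nneg = 0
    per_chrom_neg = math.ceil(config.n_negative / len(chroms))
    for chrom in chroms:
        lo = max(hi for _, hi in [loci.get(chrom, (0, 4_400_000))]) + 100_000
        for pos in _sample_positions(rng, lo, config.chrom_lengths[chrom] - 1_000, per_chrom_neg):
            if nneg >= config.n_negative or (chrom, int(pos)) in used:
                continue
            used.add((chrom, int(pos)))
            negatives.append((f"neg_{nneg}", chrom, int(pos)))
            nneg += 1

    # ---------------- role assignment ----------------
    all_proxy_keys = sorted(proxies)
    if config.plant_genes:
        # twelve SNPs that will carry predicted target genes; tag indices pin
        # their disease labels (tags 0-3 RA, 4-7 psoriasis, 8-11 UC)
        with_target_keys = [
            (0, 1),  # s1: local
            (1, 1),  # s2: local
            (0, 2),  # s3: distal, candidate drug gene A1 (RA)
            (4, 0),  # s4: distal, gene encoding TFC (psoriasis)
            (1, 2),  # s5: distal, autoimmune drug gene C1 (RA)
            (2, 0),  # s6: distal, PPI-too-weak decoy gene (RA)
            (4, 1),  # s7: local
            (5, 1),  # s8: local
            (3, 0),  # s9: distal, non-druggable decoy gene (RA)
            (5, 0),  # s10: distal, second candidate gene A5 (psoriasis)
            (8, 0),  # s11: distal, disease-mismatch decoy gene (UC)
            (6, 0),  # s12: distal plain gene
        ]
        no_target_keys = [
            (0, 3), (1, 3), (2, 1), (2, 2), (3, 1), (3, 2),
            (6, 1), (7, 0), (7, 1), (9, 0), (10, 0), (11, 0),
        ]
        extra_needed = config.n_functional - 24
        pool = [k for k in all_proxy_keys if k not in set(with_target_keys + no_target_keys)]
        no_target_keys = no_target_keys + pool[:extra_needed]
        functional_keys = with_target_keys + no_target_keys
    else:
        with_target_keys = []
        functional_keys = all_proxy_keys[: config.n_functional]
    functional_ids = [proxies[k][0] for k in functional_keys]
    truth.functional_snps = sorted(functional_ids)

    # motif assignment: local/distal SNPs split between TFA and TFC, the
    # remaining functional SNPs carry TFB
    tf_of: dict[str, str] = {}
    for i, key in enumerate(with_target_keys):
        tf_of[proxies[key][0]] = "TFA" if i < 6 else "TFC"
    for key in functional_keys[len(with_target_keys):]:
        tf_of[proxies[key][0]] = "TFB"

    # ---------------- flanks, alleles, motif libraries ----------------
    frng = _rng(config.seed, "flanks")
    pwms = _planted_pwms(config, frng)
    L = config.motif_length
    width = 2 * config.flank_width + 1
    center = config.flank_width
    flanks: dict[str, str] = {}
    alleles: dict[str, tuple[str, str]] = {}
    positive_order = [t[0] for t in tags] + [proxies[k][0] for k in all_proxy_keys]
    for snp_id in positive_order:
        seq = "".join(BASES[i] for i in frng.integers(0, 4, size=width))
        if snp_id in tf_of:
            cons = pwms[tf_of[snp_id]].consensus
            offset = center - int(frng.integers(0, L))
            seq = seq[:offset] + cons + seq[offset + L :]
            ref = seq[center]
            alt = BASES[(BASES.index(ref) + 1 + int(frng.integers(3))) % 4]
        else:
            ref = seq[center]
            alt = BASES[(BASES.index(ref) + 1 + int(frng.integers(3))) % 4]
        flanks[snp_id] = seq
        alleles[snp_id] = (ref, alt)
    rio.write_fasta(flanks, outdir / "flanks.fasta")
    # two motif databases share the planted matrices; TFF sits in one only
    db_a = [Pwm(tf, "jaspar_like", pwms[tf].matrix) for tf in sorted(pwms)]
    db_b = [
        Pwm(tf, "hocomoco_like", pwms[tf].matrix) for tf in sorted(pwms) if tf != "TFF"
    ]
    rio.write_meme_motifs(db_a, outdir / "motifs_jaspar_like.meme")
    rio.write_meme_motifs(db_b, outdir / "motifs_hocomoco_like.meme")
    expr = pd.DataFrame(
        [
            {"tf_name": tf, "cell_type": "CD4_T", "rpkm": 0.4 if tf == "TFE" else 5.0}
            for tf in sorted(pwms)
        ]
    )
    rio.write_tsv(expr, outdir / "tf_expression.tsv")

    # ---------------- SNP / LD / catalog tables ----------------
    rows = []
    disease_of_tag = {f"tag_{i}": d for i, (_, _, _, d) in enumerate(tags)}
    for tag_id, chrom, pos, disease in tags:
        ref, alt = alleles[tag_id]
        rows.append((tag_id, chrom, pos, ref, alt, alt, disease, 0, "tag"))
    for (ti, k), (snp_id, chrom, pos) in sorted(proxies.items()):
        ref, alt = alleles[snp_id]
        rows.append((snp_id, chrom, pos, ref, alt, alt, tags[ti][3], 0, "proxy"))
    srng = _rng(config.seed, "ld")
    for snp_id, chrom, pos in background:
        ref, alt = _random_alleles(srng)
        rows.append((snp_id, chrom, pos, ref, alt, "", "", 0, "background"))
    for snp_id, chrom, pos in negatives:
        ref, alt = _random_alleles(srng)
        rows.append((snp_id, chrom, pos, ref, alt, "", "", 0, "negative"))
    # decoys: a coding proxy-like SNP and an outside SNP in moderate catalog LD
    chrom0 = chroms[0]
    rows.append(("coding_1", chrom0, tags[0][2] + 500, "A", "G", "", "", 1, "coding"))
    excl_pos = config.chrom_lengths[chrom0] - 500
    rows.append(("excl_ld_1", chrom0, excl_pos, "A", "G", "", "", 0, "excluded_decoy"))
    snp_df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "ref", "alt", "risk", "diseases", "coding", "role"],
    )
    rio.write_tsv(snp_df.drop(columns=["role"]), outdir / "snps.tsv")
    rio.write_tsv(snp_df[snp_df.role == "tag"][["snp_id"]], outdir / "tags.tsv")
    rio.write_tsv(snp_df[snp_df.role == "tag"][["snp_id"]], outdir / "catalog.tsv")
    ld_rows = []
    for (ti, k), (snp_id, chrom, pos) in sorted(proxies.items()):
        r2 = 0.85 + 0.1 * float(srng.random())
        ld_rows.append((tags[ti][0], snp_id, round(r2, 4), abs(pos - tags[ti][2])))
    for ti in range(config.n_tags):  # low-LD neighbours stay background
        tag_id, chrom, pos, _ = tags[ti]
        ld_rows.append((tag_id, f"bg_{ti}", 0.5, 10_000))
    ld_rows.append(("tag_0", "excl_ld_1", 0.2, excl_pos - tags[0][2]))
    rio.write_tsv(
        pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2", "distance_bp"]),
        outdir / "ld.tsv",
    )
    truth.class_counts = {
        "positive": len(tags) + len(proxies),
        "background": len(background),
        "negative": len(negatives),
        "excluded": 2,
    }

    # ---------------- epigenetic features ----------------
    erng = _rng(config.seed, "features")
    cov = min(0.95, config.target_fc * config.bg_coverage)
    n_pos = len(tags) + len(proxies)
    n_cov_pos = max(len(functional_ids), round(cov * n_pos))
    n_cov_bg = round(config.bg_coverage * len(background))
    n_null_pos = round(config.bg_coverage * n_pos)
    pos_lookup = {
        snp_id: (chrom, pos)
        for snp_id, chrom, pos in (
            [(t[0], t[1], t[2]) for t in tags]
            + [proxies[k] for k in all_proxy_keys]
            + background
        )
    }
    non_functional_pos = [
        s for s in positive_order if s not in set(functional_ids)
    ]
    manifest_rows = []
    for ci, category in enumerate(CATEGORIES):
        for j in range(config.n_enriched_per_category + config.n_null_per_category):
            enriched = j < config.n_enriched_per_category
            cell = CELL_TYPES[(ci + j) % len(CELL_TYPES)]
            feature_id = f"{category}_{cell}_{'enr' if enriched else 'null'}_{j}"
            if enriched:
                extras = list(
                    erng.choice(
                        non_functional_pos,
                        size=min(len(non_functional_pos), n_cov_pos - len(functional_ids)),
                        replace=False,
                    )
                )
                covered = functional_ids + extras
            else:
                covered = list(
                    erng.choice(positive_order, size=n_null_pos, replace=False)
                )
            covered_bg = list(
                erng.choice([s for s, _, _ in background], size=n_cov_bg, replace=False)
            )
            ivs = []
            for snp_id in covered + covered_bg:
                chrom, pos = pos_lookup[snp_id]
                ivs.append((chrom, pos - 11, pos + 10))
            bed = outdir / "features" / f"{feature_id}.bed"
            with open(bed, "w") as fh:
                for chrom, s, e in sorted(ivs):
                    fh.write(f"{chrom}\t{s}\t{e}\t{feature_id}\n")
            manifest_rows.append(
                {
                    "feature_id": feature_id,
                    "category": category,
                    "cell_type": cell,
                    "bed_path": f"features/{feature_id}.bed",
                }
            )
            if enriched:
                truth.enriched_features.append(feature_id)
    rio.write_tsv(pd.DataFrame(manifest_rows), outdir / "feature_manifest.tsv")
    truth.enriched_features.sort()

    # ---------------- molecular QTL ----------------
    qrng = _rng(config.seed, "molecular_qtl")
    mq_rows = []
    for snp_id in functional_ids[: min(6, len(functional_ids))]:
        chrom, pos = pos_lookup[snp_id]
        mq_rows.append(
            (snp_id, chrom, pos, "caQTL", "monocyte", "caqtl_d1", chrom, pos - 101, pos + 100, 1e-6, 0.02)
        )
    if functional_ids:
        chrom, pos = pos_lookup[functional_ids[0]]
        # distal peak and non-significant decoy rows
        mq_rows.append(
            (functional_ids[0], chrom, pos, "hQTL", "LCL", "hqtl_d1", chrom, pos + 10_000, pos + 10_400, 1e-8, 0.001)
        )
        mq_rows.append(
            (functional_ids[0], chrom, pos, "dsQTL", "LCL", "dsqtl_d1", chrom, pos - 101, pos + 100, 0.2, 0.5)
        )
    rio.write_tsv(
        pd.DataFrame(
            mq_rows,
            columns=[
                "snp_id", "chrom", "pos", "assay", "cell_type", "dataset_id",
                "peak_chrom", "peak_start", "peak_end", "p", "fdr",
            ],
        ),
        outdir / "molecular_qtl.tsv",
    )

    # ---------------- genes, cis-QTL, contacts, coloc ----------------
    grng = _rng(config.seed, "genes")
    gene_rows = []
    cis_rows = []
    contact_rows = []
    coloc_specs = []  # (gene_id, gwas_id, qtl_id, kind)
    tf_gene_map_rows = []
    gene_serial = [0]

    def _add_gene(symbol: str, chrom: str, tss: int) -> str:
        gene_id = f"G{gene_serial[0]:03d}"
        gene_serial[0] += 1
        gene_rows.append(
            {"gene_id": gene_id, "symbol": symbol, "chrom": chrom,
             "strand": "+" if grng.random() < 0.5 else "-", "tss_list": str(tss)}
        )
        return gene_id

    def _add_cis(snp_id: str, gene_id: str, datasets: list[str]) -> None:
        for d in datasets:
            cis_rows.append(
                {"snp_id": snp_id, "gene_id": gene_id, "dataset_id": d,
                 "cell_type": "CD4_T", "qtl_type": "eQTL", "beta": 0.4,
                 "se": 0.05, "p": 1e-6, "fdr": 0.001}
            )

    def _add_contacts(snp_id: str, tss: int, chrom: str, datasets: list[str]) -> None:
        _, pos = pos_lookup[snp_id]
        for d in datasets:
            contact_rows.append(
                (chrom, pos - 5_000, pos + 5_000, chrom, tss - 1_500, tss + 1_500, d, "hic")
            )

    if config.plant_genes:
        disease_of_snp = {}
        for (ti, k) in all_proxy_keys:
            disease_of_snp[proxies[(ti, k)][0]] = tags[ti][3]
        s = [proxies[k][0] for k in with_target_keys]  # s[0] == s1 ... s[11] == s12
        local_gene_of = {}
        for snp_id in (s[0], s[1], s[6], s[7]):
            chrom, pos = pos_lookup[snp_id]
            gid = _add_gene(f"LOC_{snp_id}", chrom, pos - 200)
            local_gene_of[snp_id] = gid
            _add_cis(snp_id, gid, ["eqtl_d1", "eqtl_d2"])
            coloc_specs.append((gid, "gwas_1", "eqtl_d1", "shared"))
            truth.snp_gene_pairs.append({"snp": snp_id, "gene": gid, "class": "local"})
            truth.local_genes.append(gid)
        distal_gene_of = {}
        for i, snp_id in enumerate((s[2], s[3], s[4], s[5], s[8], s[9], s[10], s[11])):
            chrom, pos = pos_lookup[snp_id]
            tss = pos + 150_000 + 1_000 * i
            symbol = "TFC" if snp_id == s[3] else f"DIST_{snp_id}"
            gid = _add_gene(symbol, chrom, tss)
            distal_gene_of[snp_id] = gid
            _add_cis(snp_id, gid, ["eqtl_d1", "eqtl_d2"])
            _add_contacts(snp_id, tss, chrom, ["hic_1", "hic_2"])
            coloc_specs.append((gid, "gwas_1", "eqtl_d1", "shared"))
            truth.snp_gene_pairs.append({"snp": snp_id, "gene": gid, "class": "distal"})
            truth.distal_genes.append(gid)
        # TF gene mapping: TFC is encoded by the planted distal gene; the
        # other TFs map to filler genes created below
        tfc_gene = distal_gene_of[s[3]]
        # decoy genes, each lacking exactly one evidence leg
        chrom, pos = pos_lookup[s[11]]
        dec1 = _add_gene("DEC_QTL1", chrom, pos + 300_000)
        _add_cis(s[11], dec1, ["eqtl_d1"])  # only one dataset
        _add_contacts(s[11], pos + 300_000, chrom, ["hic_1", "hic_2"])
        coloc_specs.append((dec1, "gwas_1", "eqtl_d1", "shared"))
        chrom, pos = pos_lookup[s[5]]
        dec2 = _add_gene("DEC_COLOC", chrom, pos + 320_000)
        _add_cis(s[5], dec2, ["eqtl_d1", "eqtl_d2"])
        _add_contacts(s[5], pos + 320_000, chrom, ["hic_1", "hic_2"])
        coloc_specs.append((dec2, "gwas_1", "eqtl_d1", "distinct"))
        chrom, pos = pos_lookup[s[8]]
        dec3 = _add_gene("DEC_CONTACT", chrom, pos + 340_000)
        _add_cis(s[8], dec3, ["eqtl_d1", "eqtl_d2"])
        _add_contacts(s[8], pos + 340_000, chrom, ["hic_1"])  # one dataset only
        coloc_specs.append((dec3, "gwas_1", "eqtl_d1", "shared"))
        inert = non_functional_pos[0]
        chrom, pos = pos_lookup[inert]
        dec4 = _add_gene("DEC_INERT", chrom, pos + 360_000)
        _add_cis(inert, dec4, ["eqtl_d1", "eqtl_d2"])
        _add_contacts(inert, pos + 360_000, chrom, ["hic_1", "hic_2"])
        coloc_specs.append((dec4, "gwas_1", "eqtl_d1", "shared"))
        truth.enriched_tfs = ["TFA", "TFC"]
    fillers = []
    for i in range(config.n_filler_genes):
        chrom = chroms[i % len(chroms)]
        tss = 1_200_000 + 60_000 * i
        fillers.append(_add_gene(f"FILLER_{i}", chrom, tss))
    if config.plant_genes:
        tf_gene_map_rows = [
            {"tf_name": "TFA", "gene_id": fillers[0]},
            {"tf_name": "TFB", "gene_id": fillers[1]},
            {"tf_name": "TFC", "gene_id": tfc_gene},
        ]
    rio.write_tsv(pd.DataFrame(gene_rows), outdir / "genes.tsv")
    rio.write_tsv(
        pd.DataFrame(
            cis_rows,
            columns=["snp_id", "gene_id", "dataset_id", "cell_type", "qtl_type",
                     "beta", "se", "p", "fdr"],
        ),
        outdir / "cis_qtl.tsv",
    )
    with open(outdir / "contacts.bedpe", "w") as fh:
        for row in contact_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    rio.write_tsv(
        pd.DataFrame(tf_gene_map_rows, columns=["tf_name", "gene_id"]),
        outdir / "tf_genes.tsv",
    )

    crng = _rng(config.seed, "coloc")
    sum_rows = []
    for gene_id, gwas_id, qtl_id, kind in coloc_specs:
        gwas, qtl = generate_coloc_scenario(
            kind, n=config.coloc_n, effect=config.coloc_effect,
            snps=config.coloc_snps, seed=crng,
        )
        for gw, qw in zip(gwas.itertuples(index=False), qtl.itertuples(index=False)):
            sum_rows.append(
                {"locus_id": f"locus_{gene_id}", "gene_id": gene_id,
                 "gwas_id": gwas_id, "qtl_id": qtl_id, "snp_id": gw.snp_id,
                 "beta_gwas": gw.beta, "se_gwas": gw.se, "beta_qtl": qw.beta,
                 "se_qtl": qw.se, "n": gw.n, "freq": gw.freq}
            )
    rio.write_tsv(
        pd.DataFrame(
            sum_rows,
            columns=["locus_id", "gene_id", "gwas_id", "qtl_id", "snp_id",
                     "beta_gwas", "se_gwas", "beta_qtl", "se_qtl", "n", "freq"],
        ),
        outdir / "coloc_summaries.tsv",
    )

    # ---------------- gene function, pathways, drugs, PPI ----------------
    all_gene_ids = [g["gene_id"] for g in gene_rows]
    ann_rows = []
    for i, gid in enumerate(all_gene_ids):
        ann_rows.append(
            {"gene_id": gid,
             "pathway_immune": int(i % 3 == 0),
             "impc_immune": int(i % 5 == 0),
             "omim_immune": int(i % 7 == 0),
             "disgenet_immune": int(i % 4 == 0),
             "rpkm_max": 5.0 if i % 2 == 0 else 0.3,
             "tsea_psi": 0.005 if i % 6 == 0 else 0.5,
             "smr_fdr": 0.01 if i % 3 == 1 else 0.8,
             "smr_heidi_p": 0.5}
        )
    rio.write_tsv(pd.DataFrame(ann_rows), outdir / "gene_annotations.tsv")
    prng = _rng(config.seed, "function")
    path_rows = []
    pathway_members = {
        "immune_pathway_1": all_gene_ids[: max(4, len(all_gene_ids) // 2)],
        "housekeeping_1": fillers,
    }
    for pw, members in pathway_members.items():
        for gid in members:
            path_rows.append({"pathway_id": pw, "gene_id": gid})
    rio.write_tsv(pd.DataFrame(path_rows), outdir / "pathways.tsv")

    drug_rows = []
    druggable_rows = []
    ppi_rows = []
    if config.plant_genes:
        a1 = distal_gene_of[s[2]]
        c2 = distal_gene_of[s[3]]
        c1 = distal_gene_of[s[4]]
        a2 = distal_gene_of[s[5]]
        a4 = distal_gene_of[s[8]]
        a5 = distal_gene_of[s[9]]
        mism = distal_gene_of[s[10]]
        drug_rows += [
            {"gene_id": c1, "drug_id": "drug_C1", "indication": "rheumatoid_arthritis"},
            {"gene_id": c2, "drug_id": "drug_C2", "indication": "psoriasis"},
            {"gene_id": a1, "drug_id": "drug_A1", "indication": "oncology"},
            {"gene_id": fillers[2], "drug_id": "drug_F", "indication": "allergy"},
        ]
        druggable_rows += [
            {"gene_id": a1, "resource": "dgidb"},
            {"gene_id": a1, "resource": "pharos"},
            {"gene_id": a2, "resource": "dgidb"},
            {"gene_id": a2, "resource": "pharos"},
            {"gene_id": a4, "resource": "dgidb"},  # one resource: not druggable
            {"gene_id": a5, "resource": "dgidb"},
            {"gene_id": a5, "resource": "finan"},
            {"gene_id": mism, "resource": "dgidb"},
            {"gene_id": mism, "resource": "pharos"},
        ]
        ppi_rows += [
            {"gene_a": a1, "gene_b": c1, "score": 0.95},
            {"gene_a": a2, "gene_b": c1, "score": 0.85},
            {"gene_a": a4, "gene_b": c1, "score": 0.95},
            {"gene_a": mism, "gene_b": c1, "score": 0.95},
            {"gene_a": a5, "gene_b": c2, "score": 0.92},
            {"gene_a": fillers[3], "gene_b": fillers[4], "score": 0.99},
        ]
        truth.drug_triples = sorted(
            [
                [a1, "rheumatoid_arthritis", [c1]],
                [a5, "psoriasis", [c2]],
            ]
        )
    rio.write_tsv(
        pd.DataFrame(drug_rows, columns=["gene_id", "drug_id", "indication"]),
        outdir / "drug_targets.tsv",
    )
    rio.write_tsv(
        pd.DataFrame(druggable_rows, columns=["gene_id", "resource"]),
        outdir / "druggability.tsv",
    )
    rio.write_tsv(
        pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "score"]),
        outdir / "ppi.tsv",
    )
    rio.write_tsv(
        pd.DataFrame(
            [
                {"indication": "rheumatoid_arthritis", "class": "autoimmune"},
                {"indication": "psoriasis", "class": "autoimmune"},
                {"indication": "ulcerative_colitis", "class": "autoimmune"},
                {"indication": "allergy", "class": "immune_related"},
                {"indication": "oncology", "class": "other"},
            ]
        ),
        outdir / "indication_classes.tsv",
    )
    truth.local_genes.sort()
    truth.distal_genes.sort()
    truth.snp_gene_pairs.sort(key=lambda d: (d["snp"], d["gene"]))
    truth.to_json(outdir / "truth.json")
    return truth
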