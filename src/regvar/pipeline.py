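"""Pipeline configuration, stage orchestration, and summary reporting.

The pipeline runs seven stages - curate, score, allelic, genes, tfnet, drugs,
report - over a directory of input tables (the synthetic generator emits the
same layout). Every stage writes plain-text TSV/JSON intermediates into the
artifact directory and is skipped on re-run when its outputs already exist,
so a deleted intermediate recomputes only the downstream stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .allelic_evidence import (
    call_allelic_motifs,
    filter_molecular_qtl,
    prioritize_functional_snps,
)
from .coloc import coloc_abf
from .core import SnpClass, promoter_windows
from .drug_function import (
    annotate_gene_function,
    build_drug_annotations,
    ora_test,
    predict_new_drug_targets,
)
from .epigenetic_scoring import (
    CATEGORIES,
    EpigeneticFeature,
    annotation_matrix,
    enrich_features,
    null_support,
    score_matrix,
)
from .snp_curation import classify_snps, define_loci, expand_tags
from .target_genes import filter_cis_qtl, predict_target_genes
from .tf_network import assign_tf_targets, enrich_tfs, shared_target_matrix

logger = logging.getLogger(__name__)

STAGES = ("curate", "score", "allelic", "genes", "tfnet", "drugs", "report")


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    r2_min: float = 0.8
    ld_max_dist: int = 1_000_000
    catalog_r2_max: float = 0.1
    feature_alpha: float = 0.05
    null_quantile: float = 0.95
    motif_p_threshold: float = 1e-4
    molecular_fdr_max: float = 0.1
    cis_fdr_max: float = 0.05
    min_qtl_datasets: int = 2
    min_interaction_datasets: int = 2
    pp4_min: float = 0.8
    promoter_half_width: int = 1000
    ppi_min: float = 0.9
    # enrichment denominator: count positives inside the background universe
    # (all noncoding SNPs in the loci), mirroring how locus-wide totals are
    # tallied; set False for a strictly disjoint background group
    background_includes_positives: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _outputs(config: PipelineConfig, *names: str) -> list[Path]:
    return [Path(config.out_dir) / name for name in names]


def _done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


# ---------------------------------------------------------------------------


def stage_curate(config: PipelineConfig, force: bool = False) -> bool:
    out_classes, out_loci = _outputs(config, "snp_classes.tsv", "loci.bed")
    if not force and _done([out_classes, out_loci]):
        logger.info("curate: outputs present, skipped")
        return False
    indir = Path(config.input_dir)
    snps = rio.read_snp_table(indir / "snps.tsv")
    tag_ids = set(rio.read_tsv(indir / "tags.tsv")["snp_id"])
    catalog_ids = set(rio.read_tsv(indir / "catalog.tsv")["snp_id"])
    ld = rio.read_tsv(indir / "ld.tsv")
    tags = [snps[i] for i in sorted(tag_ids) if i in snps]
    positives = expand_tags(
        tags, snps, ld, r2_min=config.r2_min, max_dist=config.ld_max_dist
    )
    loci = define_loci(tags, flank=config.ld_max_dist)
    max_cat = {}
    for row in ld.itertuples(index=False):
        for a, b in ((row.snp_a, row.snp_b), (row.snp_b, row.snp_a)):
            if a in catalog_ids:
                max_cat[b] = max(max_cat.get(b, 0.0), float(row.r2))
    classes = classify_snps(
        snps, loci, positives, max_cat, catalog_r2_max=config.catalog_r2_max
    )
    rows = []
    for snp_id in sorted(snps):
        rec = positives.get(snp_id, snps[snp_id])
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "snp_class": classes[snp_id].value,
                "diseases": ",".join(sorted(rec.diseases)),
            }
        )
    rio.write_tsv(pd.DataFrame(rows), out_classes)
    rio.write_bed(loci.loci, out_loci)
    return True


def _load_classes(config: PipelineConfig) -> pd.DataFrame:
    return rio.read_tsv(Path(config.out_dir) / "snp_classes.tsv", keep_default_na=False)


def _snps_of_class(config: PipelineConfig, cls: SnpClass):
    from .core import SnpRecord

    df = _load_classes(config)
    sel = df[df.snp_class == cls.value]
    return [
        SnpRecord(
            snp_id=r.snp_id,
            chrom=r.chrom,
            pos=int(r.pos),
            diseases=set(r.diseases.split(",")) if r.diseases else set(),
        )
        for r in sel.itertuples(index=False)
    ]


def stage_score(
    config: PipelineConfig, force: bool = False, negative_chunk: int = 200_000
) -> bool:
    outs = _outputs(config, "enrichment.tsv", "scores.tsv", "thresholds.tsv")
    if not force and _done(outs):
        logger.info("score: outputs present, skipped")
        return False
    indir = Path(config.input_dir)
    manifest = rio.read_tsv(indir / "feature_manifest.tsv")
    features = [
        EpigeneticFeature(
            feature_id=row.feature_id,
            category=row.category,
            cell_type=row.cell_type,
            peaks=rio.read_bed(indir / row.bed_path),
        )
        for row in manifest.itertuples(index=False)
    ]
    positives = _snps_of_class(config, SnpClass.POSITIVE)
    background = _snps_of_class(config, SnpClass.BACKGROUND)
    negatives = _snps_of_class(config, SnpClass.NEGATIVE)
    bg_universe = (
        background + positives if config.background_includes_positives else background
    )
    enr = enrich_features(positives, bg_universe, features, alpha=config.feature_alpha)
    rio.write_tsv(
        pd.DataFrame(
            [
                {
                    "feature_id": e.feature_id,
                    "category": e.category,
                    "annotated_pos": e.table.a,
                    "annotated_bg": e.table.c,
                    "fc": e.fc,
                    "p": e.p,
                    "p_adj": e.p_adj,
                    "selected": e.selected,
                }
                for e in enr
            ]
        ),
        outs[0],
    )
    selected = {e.feature_id for e in enr if e.selected}
    fc_of = {e.feature_id: e.fc for e in enr}
    score_rows = {s.snp_id: {"snp_id": s.snp_id} for s in positives}
    thr_rows = []
    for category in CATEGORIES:
        feats = [f for f in features if f.category == category and f.feature_id in selected]
        weights = np.array([fc_of[f.feature_id] for f in feats])
        pos_scores = score_matrix(annotation_matrix(positives, feats), weights)
        # negatives scored in bounded-memory chunks
        neg_scores = np.concatenate(
            [
                score_matrix(annotation_matrix(list(chunk), feats), weights)
                for chunk in (
                    negatives[i : i + negative_chunk]
                    for i in range(0, len(negatives), negative_chunk)
                )
            ]
        ) if negatives else np.array([0.0])
        threshold, flags = null_support(pos_scores, neg_scores, config.null_quantile)
        thr_rows.append({"category": category, "null_threshold": threshold})
        for snp, sc, fl in zip(positives, pos_scores, flags):
            score_rows[snp.snp_id][f"score_{category}"] = sc
            score_rows[snp.snp_id][f"support_{category}"] = bool(fl)
    rio.write_tsv(pd.DataFrame(list(score_rows.values())), outs[1])
    rio.write_tsv(pd.DataFrame(thr_rows), outs[2])
    return True


def stage_allelic(config: PipelineConfig, force: bool = False) -> bool:
    outs = _outputs(config, "motif_calls.tsv", "functional.tsv")
    if not force and _done(outs):
        logger.info("allelic: outputs present, skipped")
        return False
    indir = Path(config.input_dir)
    flanks = rio.read_fasta(indir / "flanks.fasta")
    pwms = []
    for meme in sorted(indir.glob("motifs_*.meme")):
        pwms.extend(rio.read_meme_motifs(meme, database=meme.stem.replace("motifs_", "")))
    expr = rio.read_tsv(indir / "tf_expression.tsv")
    expressed = set(expr[expr.rpkm > 1.0]["tf_name"].str.upper())
    positives = _snps_of_class(config, SnpClass.POSITIVE)
    snp_alleles = rio.read_snp_table(indir / "snps.tsv")
    calls = []
    scanners: dict[int, object] = {}
    for snp in positives:
        flank = flanks.get(snp.snp_id)
        if flank is None:
            logger.warning("no flank sequence for %s; skipped", snp.snp_id)
            continue
        rec = snp_alleles[snp.snp_id]
        calls.extend(
            call_allelic_motifs(
                rec,
                flank,
                pwms,
                expressed_tfs=expressed,
                p_threshold=config.motif_p_threshold,
                scanners=scanners,
            )
        )
    rio.write_tsv(
        pd.DataFrame(
            [
                {
                    "snp_id": c.snp_id,
                    "tf_name": c.tf_name,
                    "direction": c.direction,
                    "n_databases": len(c.supporting_databases),
                    "expressed_tf": c.expressed_tf,
                    "retained": c.retained,
                }
                for c in calls
            ],
            columns=["snp_id", "tf_name", "direction", "n_databases", "expressed_tf", "retained"],
        ),
        outs[0],
    )
    mq, _ = filter_molecular_qtl(
        rio.read_tsv(indir / "molecular_qtl.tsv"), fdr_max=config.molecular_fdr_max
    )
    scores = rio.read_tsv(Path(config.out_dir) / "scores.tsv")
    epi = {
        row.snp_id: {c for c in CATEGORIES if getattr(row, f"support_{c}")}
        for row in scores.itertuples(index=False)
    }
    fcalls = prioritize_functional_snps(
        [s.snp_id for s in positives], epi, calls, mq
    )
    rio.write_tsv(
        pd.DataFrame(
            [
                {
                    "snp_id": f.snp_id,
                    "n_categories": len(f.epigenetic_categories),
                    "evidence": ",".join(sorted(f.allelic_evidence)),
                    "functional": f.functional,
                }
                for f in fcalls
            ]
        ),
        outs[1],
    )
    return True


def stage_genes(config: PipelineConfig, force: bool = False) -> bool:
    outs = _outputs(config, "coloc.tsv", "pairs.tsv", "gene_classes.tsv")
    if not force and _done(outs):
        logger.info("genes: outputs present, skipped")
        return False
    indir = Path(config.input_dir)
    genes = rio.read_gene_models(indir / "genes.tsv")
    promoters = promoter_windows(genes.values(), config.promoter_half_width)
    by_gene: dict[str, list] = {}
    for iv in promoters:
        by_gene.setdefault(iv.label, []).append(iv)
    cis = rio.read_tsv(indir / "cis_qtl.tsv")
    _, pair_counts = filter_cis_qtl(
        cis, genes, fdr_max=config.cis_fdr_max, min_datasets=config.min_qtl_datasets
    )
    contacts = rio.read_bedpe(indir / "contacts.bedpe")
    summaries = rio.read_tsv(indir / "coloc_summaries.tsv")
    coloc_rows = []
    pp4_by_gene: dict[str, float] = {}
    for (gene_id, gwas_id, qtl_id), grp in summaries.groupby(
        ["gene_id", "gwas_id", "qtl_id"]
    ):
        gwas = grp[["snp_id", "beta_gwas", "se_gwas"]].rename(
            columns={"beta_gwas": "beta", "se_gwas": "se"}
        )
        qtl = grp[["snp_id", "beta_qtl", "se_qtl"]].rename(
            columns={"beta_qtl": "beta", "se_qtl": "se"}
        )
        res = coloc_abf(
            gwas, qtl, locus_id=str(grp["locus_id"].iloc[0]), gene_id=gene_id,
            dataset_pair=(gwas_id, qtl_id),
        )
        coloc_rows.append(
            {"gene_id": gene_id, "gwas_id": gwas_id, "qtl_id": qtl_id,
             **{f"pp{k}": res.pp[k] for k in range(5)}}
        )
        pp4_by_gene[gene_id] = max(pp4_by_gene.get(gene_id, 0.0), res.pp4)
    rio.write_tsv(pd.DataFrame(coloc_rows), outs[0])
    func = rio.read_tsv(Path(config.out_dir) / "functional.tsv")
    functional = set(func[func["functional"].astype(bool)]["snp_id"])
    classes = _load_classes(config)
    snp_positions = {
        r.snp_id: (r.chrom, int(r.pos)) for r in classes.itertuples(index=False)
    }
    pairs, gene_table = predict_target_genes(
        functional,
        snp_positions,
        pair_counts,
        contacts,
        pp4_by_gene,
        by_gene,
        pp4_min=config.pp4_min,
        min_qtl_datasets=config.min_qtl_datasets,
        min_interaction_datasets=config.min_interaction_datasets,
    )
    rio.write_tsv(
        pd.DataFrame(
            [
                {
                    "snp_id": p.snp_id,
                    "gene_id": p.gene_id,
                    "pair_class": p.pair_class,
                    "qtl_dataset_count": p.qtl_dataset_count,
                    "interaction_dataset_count": p.interaction_dataset_count,
                    "coloc_pp4_max": p.coloc_pp4_max,
                    "predicted": p.predicted,
                }
                for p in pairs
            ],
            columns=["snp_id", "gene_id", "pair_class", "qtl_dataset_count",
                     "interaction_dataset_count", "coloc_pp4_max", "predicted"],
        ),
        outs[1],
    )
    rio.write_tsv(gene_table, outs[2])
    return True


def stage_tfnet(config: PipelineConfig, force: bool = False) -> bool:
    outs = _outputs(config, "tf_enrichment.tsv", "tf_edges.tsv", "tf_shared.tsv")
    if not force and _done(outs):
        logger.info("tfnet: outputs present, skipped")
        return False
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    calls = rio.read_tsv(outdir / "motif_calls.tsv")
    retained = calls[calls["retained"].astype(bool)]
    calls_by_snp: dict[str, set] = {}
    for row in retained.itertuples(index=False):
        calls_by_snp.setdefault(row.snp_id, set()).add(row.tf_name)
    classes = _load_classes(config)
    positives = set(classes[classes.snp_class == "positive"]["snp_id"])
    pairs = rio.read_tsv(outdir / "pairs.tsv")
    predicted = pairs[pairs["predicted"].astype(bool)]
    with_targets = set(predicted["snp_id"])
    func_calls = {s: calls_by_snp.get(s, set()) for s in with_targets}
    pos_calls = {s: calls_by_snp.get(s, set()) for s in positives}
    enr = enrich_tfs(func_calls, pos_calls, alpha=0.05)
    rio.write_tsv(
        pd.DataFrame(
            [
                {"tf_name": e.tf_name, "a": e.table.a, "c": e.table.c,
                 "fc": e.fc, "p": e.p, "p_adj": e.p_adj, "enriched": e.enriched}
                for e in enr
            ],
            columns=["tf_name", "a", "c", "fc", "p", "p_adj", "enriched"],
        ),
        outs[0],
    )
    tf_map_df = rio.read_tsv(indir / "tf_genes.tsv")
    tf_map = dict(zip(tf_map_df.get("tf_name", []), tf_map_df.get("gene_id", [])))
    edges = assign_tf_targets(
        [e.tf_name for e in enr if e.enriched], calls_by_snp, predicted, tf_map
    )
    rio.write_tsv(
        pd.DataFrame(
            [
                {"tf_name": e.tf_name, "gene_id": e.gene_id, "model": e.model, "via": e.via}
                for e in edges
            ],
            columns=["tf_name", "gene_id", "model", "via"],
        ),
        outs[1],
    )
    matrix, cover = shared_target_matrix(edges)
    matrix.insert(0, "tf_name", matrix.index)
    matrix["in_cover"] = [tf in cover for tf in matrix["tf_name"]]
    rio.write_tsv(matrix.reset_index(drop=True), outs[2])
    return True


def stage_drugs(config: PipelineConfig, force: bool = False) -> bool:
    outs = _outputs(config, "gene_function.tsv", "ora.tsv", "drug_predictions.tsv")
    if not force and _done(outs):
        logger.info("drugs: outputs present, skipped")
        return False
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    genes = rio.read_gene_models(indir / "genes.tsv")
    gene_table = rio.read_tsv(outdir / "gene_classes.tsv")
    predicted_genes = list(gene_table["gene_id"]) if len(gene_table) else []
    ann = annotate_gene_function(
        predicted_genes, rio.read_tsv(indir / "gene_annotations.tsv")
    )
    rio.write_tsv(
        pd.DataFrame([dataclasses.asdict(a) for a in ann]), outs[0]
    )
    path_df = rio.read_tsv(indir / "pathways.tsv")
    pathways: dict[str, set] = {
        pw: set(grp["gene_id"]) for pw, grp in path_df.groupby("pathway_id")
    }
    universe = set(genes)
    ora = ora_test(set(predicted_genes) & universe, pathways, universe)
    rio.write_tsv(ora, outs[1])
    records = build_drug_annotations(
        rio.read_tsv(indir / "drug_targets.tsv"),
        rio.read_tsv(indir / "druggability.tsv"),
        rio.read_tsv(indir / "indication_classes.tsv"),
    )
    pairs = rio.read_tsv(outdir / "pairs.tsv")
    classes = _load_classes(config)
    snp_diseases = {
        r.snp_id: set(r.diseases.split(",")) if r.diseases else set()
        for r in classes.itertuples(index=False)
    }
    gene_diseases: dict[str, set] = {}
    for row in pairs[pairs["predicted"].astype(bool)].itertuples(index=False):
        gene_diseases.setdefault(row.gene_id, set()).update(
            snp_diseases.get(row.snp_id, set())
        )
    preds = predict_new_drug_targets(
        gene_diseases, records, rio.read_tsv(indir / "ppi.tsv"), ppi_min=config.ppi_min
    )
    rio.write_tsv(
        pd.DataFrame(
            [
                {
                    "candidate_gene": p.candidate_gene,
                    "disease": p.disease,
                    "partner_genes": ",".join(p.partner_genes),
                    "repurposing_flag": p.repurposing_flag,
                }
                for p in preds
            ],
            columns=["candidate_gene", "disease", "partner_genes", "repurposing_flag"],
        ),
        outs[2],
    )
    return True


def round_half_up(x: float, ndigits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float | None:
    """Half-up-rounded percentage; None when the denominator is zero."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, ndigits)


def summarize_results(
    pairs: pd.DataFrame,
    gene_table: pd.DataFrame,
    tf_edges: pd.DataFrame,
    drug_predictions: pd.DataFrame,
    gene_models: dict | None = None,
    snp_positions: dict[str, tuple[str, int]] | None = None,
    distal_cut_bp: int = 50_000,
) -> dict:
    """Summary counts, percentages and distance statistics.

    Percentages are recomputed from the report's own counts (half-up, one
    decimal headline / two decimals in tables); pair distances are measured
    to the nearest TSS of the target gene.
    """
    if "predicted" in pairs:
        predicted = pairs[pairs["predicted"].astype(bool)]
    else:
        predicted = pairs
    n_local_pairs = int((predicted.pair_class == "local").sum())
    n_distal_pairs = int((predicted.pair_class == "distal").sum())
    n_local_genes = int((gene_table.gene_class == "local").sum()) if len(gene_table) else 0
    n_distal_genes = int((gene_table.gene_class == "distal").sum()) if len(gene_table) else 0
    report: dict = {
        "n_pairs": n_local_pairs + n_distal_pairs,
        "n_local_pairs": n_local_pairs,
        "n_distal_pairs": n_distal_pairs,
        "n_genes": n_local_genes + n_distal_genes,
        "n_local_genes": n_local_genes,
        "n_distal_genes": n_distal_genes,
        "distal_gene_pct": percentage(n_distal_genes, n_local_genes + n_distal_genes, 1),
        "distal_pair_pct": percentage(n_distal_pairs, n_local_pairs + n_distal_pairs, 2),
    }
    if gene_models is not None and snp_positions is not None and len(predicted):
        distances = []
        for row in predicted.itertuples(index=False):
            gene = gene_models.get(row.gene_id)
            pos = snp_positions.get(row.snp_id)
            if gene is None or pos is None:
                continue
            distances.append(min(abs(pos[1] - tss) for tss in gene.tss_list))
        distal_d = [
            d
            for d, row in zip(distances, predicted.itertuples(index=False))
            if row.pair_class == "distal"
        ]
        if distances:
            report["mean_pair_distance_kb"] = round_half_up(
                float(np.mean(distances)) / 1000.0, 2
            )
        if distal_d:
            report["distal_pairs_over_50kb_pct"] = percentage(
                sum(1 for d in distal_d if d > distal_cut_bp), len(distal_d), 2
            )
    n_targets = report["n_genes"]
    covered = len(set(tf_edges["gene_id"]) & set(gene_table["gene_id"])) if len(tf_edges) and len(gene_table) else 0
    report["tf_covered_targets"] = covered
    report["tf_coverage_pct"] = percentage(covered, n_targets, 2)
    if len(tf_edges):
        report["tf_model_tallies"] = (
            tf_edges.groupby("model")["gene_id"].count().to_dict()
        )
    report["n_drug_candidates"] = int(len(drug_predictions))
    if len(drug_predictions):
        report["drug_diseases"] = sorted(set(drug_predictions["disease"]))
    return report


def stage_report(config: PipelineConfig, force: bool = False) -> dict:
    out_json = Path(config.out_dir) / "report.json"
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    pairs = rio.read_tsv(outdir / "pairs.tsv")
    gene_table = rio.read_tsv(outdir / "gene_classes.tsv")
    tf_edges = rio.read_tsv(outdir / "tf_edges.tsv")
    drugs = rio.read_tsv(outdir / "drug_predictions.tsv")
    genes = rio.read_gene_models(indir / "genes.tsv")
    classes = _load_classes(config)
    snp_positions = {
        r.snp_id: (r.chrom, int(r.pos)) for r in classes.itertuples(index=False)
    }
    func = rio.read_tsv(outdir / "functional.tsv")
    report = summarize_results(
        pairs, gene_table, tf_edges, drugs, genes, snp_positions
    )
    report["class_counts"] = classes.groupby("snp_class")["snp_id"].count().to_dict()
    report["n_functional_snps"] = int(func["functional"].astype(bool).sum())
    report["n_epigenetic_supported"] = int((func.n_categories > 0).sum())
    with open(out_json, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


_STAGE_FUNCS = {
    "curate": stage_curate,
    "score": stage_score,
    "allelic": stage_allelic,
    "genes": stage_genes,
    "tfnet": stage_tfnet,
    "drugs": stage_drugs,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the final report (if run)."""
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    missing = [
        f
        for f in ("snps.tsv", "tags.tsv", "ld.tsv", "feature_manifest.tsv")
        if not (Path(config.input_dir) / f).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"required inputs missing from {config.input_dir}: {', '.join(missing)}"
        )
    report: dict = {}
    force = False
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("running stage %s", stage)
        result = _STAGE_FUNCS[stage](config, force=force)
        if stage == "report":
            report = result
        elif result:
            force = True  # anything recomputed invalidates downstream caches
    return report
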