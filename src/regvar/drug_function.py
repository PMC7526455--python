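"""Gene-level immunological function tiers, over-representation tests, drug
annotations, and rule-based new drug-target prediction.

Function tiers follow a two-level evidence scheme: *high* support comes from
immune pathways, mouse-knockout immune phenotypes (IMPC) or Mendelian immune
disorders (OMIM); *suggestive* support from blood expression (RPKM > 1),
tissue-specific expression (pSI < 0.01), disease-gene databases, or
Mendelian-randomization causality. Drug-target prediction emits a candidate
gene A for autoimmune disease B with partner C when (a) A has a strong PPI
(score > 0.9) with drug-target gene C indicated for B, (b) both A and C are
regulated by functional SNPs predisposing to B, and (c) A is itself a known
drug target or a druggable gene (evidence from >= 2 resources).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as _stats

from .core import adjust_pvalues

logger = logging.getLogger(__name__)


@dataclass
class GeneFunctionAnnotation:
    gene_id: str
    pathway_immune: bool = False
    impc_immune: bool = False
    omim_immune: bool = False
    expressed_blood: bool = False
    tsea_blood: bool = False
    disgenet_immune: bool = False
    smr_causal: bool = False
    tier: str = "none"  # high | suggestive | none


@dataclass
class DrugGeneRecord:
    gene_id: str
    drug_ids: set = field(default_factory=set)
    indication_classes: set = field(default_factory=set)
    indications: set = field(default_factory=set)  # (indication, class) pairs
    druggable_resource_count: int = 0

    @property
    def druggable(self) -> bool:
        return self.druggable_resource_count >= 2

    @property
    def known_drug_target(self) -> bool:
        return bool(self.drug_ids)


@dataclass(frozen=True)
class DrugPrediction:
    candidate_gene: str
    disease: str
    partner_genes: tuple  # sorted tuple of partner C genes
    rules_met: tuple = ("a", "b", "c")
    repurposing_flag: bool = False


def annotate_gene_function(
    genes: list[str],
    annotations: pd.DataFrame,
    rpkm_min: float = 1.0,
    psi_max: float = 0.01,
    smr_fdr_max: float = 0.05,
    heidi_p_min: float = 0.05,
) -> list[GeneFunctionAnnotation]:
    """Flag and tier each gene from the combined annotation table.

    ``annotations`` is indexed (or indexable) by gene_id with columns
    pathway_immune, impc_immune, omim_immune, disgenet_immune (booleans),
    rpkm_max, tsea_psi, smr_fdr, smr_heidi_p (numeric, NaN = absent). Genes
    absent from the table get tier "none".
    """
    table = annotations.set_index("gene_id") if "gene_id" in annotations else annotations
    out = []
    for gene in genes:
        ann = GeneFunctionAnnotation(gene_id=gene)
        if gene in table.index:
            row = table.loc[gene]
            ann.pathway_immune = bool(row.get("pathway_immune", False))
            ann.impc_immune = bool(row.get("impc_immune", False))
            ann.omim_immune = bool(row.get("omim_immune", False))
            ann.disgenet_immune = bool(row.get("disgenet_immune", False))
            rpkm = row.get("rpkm_max")
            ann.expressed_blood = pd.notna(rpkm) and float(rpkm) > rpkm_min
            psi = row.get("tsea_psi")
            ann.tsea_blood = pd.notna(psi) and float(psi) < psi_max
            fdr, heidi = row.get("smr_fdr"), row.get("smr_heidi_p")
            ann.smr_causal = (
                pd.notna(fdr)
                and pd.notna(heidi)
                and float(fdr) < smr_fdr_max
                and float(heidi) > heidi_p_min
            )
        if ann.pathway_immune or ann.impc_immune or ann.omim_immune:
            ann.tier = "high"
        elif (
            ann.expressed_blood
            or ann.tsea_blood
            or ann.disgenet_immune
            or ann.smr_causal
        ):
            ann.tier = "suggestive"
        out.append(ann)
    return out


def ora_test(
    gene_set: set,
    pathways: dict[str, set],
    universe: set,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway, BH-adjusted.

    p = Pr(overlap >= observed) drawing |gene_set| genes from the universe
    containing the pathway members. Empty pathways are skipped; ties in the
    BH ordering are broken by pathway id for reproducibility.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    rows = []
    for pathway_id in sorted(pathways):
        members = pathways[pathway_id] & universe
        if not members:
            continue
        overlap = len(gene_set & members)
        p = float(
            _stats.hypergeom.sf(
                overlap - 1, len(universe), len(members), len(gene_set)
            )
        )
        rows.append(
            {
                "pathway_id": pathway_id,
                "overlap": overlap,
                "pathway_size": len(members),
                "p": min(1.0, p),
            }
        )
    df = pd.DataFrame(rows, columns=["pathway_id", "overlap", "pathway_size", "p"])
    if len(df):
        df = df.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)
        df["fdr"] = adjust_pvalues(df["p"].to_numpy(), "bh")
    else:
        df["fdr"] = []
    return df


def build_drug_annotations(
    drug_table: pd.DataFrame,
    druggability_table: pd.DataFrame,
    indication_classes: pd.DataFrame,
) -> dict[str, DrugGeneRecord]:
    """Per-gene drug/druggability record assembly.

    ``drug_table``: gene_id, drug_id, indication. ``druggability_table``:
    gene_id, resource. ``indication_classes``: indication, class (autoimmune /
    immune_related / other). Unmapped indications fall into class "other".
    """
    class_map = dict(
        zip(indication_classes["indication"], indication_classes["class"])
    )
    records: dict[str, DrugGeneRecord] = {}

    def _rec(gene: str) -> DrugGeneRecord:
        return records.setdefault(gene, DrugGeneRecord(gene_id=gene))

    for row in drug_table.itertuples(index=False):
        rec = _rec(row.gene_id)
        rec.drug_ids.add(row.drug_id)
        cls = class_map.get(row.indication)
        if cls is None:
            logger.warning("indication %r unmapped; classed as other", row.indication)
            cls = "other"
        rec.indication_classes.add(cls)
        rec.indications.add((row.indication, cls))
    counts = druggability_table.groupby("gene_id")["resource"].nunique()
    for gene, n in counts.items():
        _rec(gene).druggable_resource_count = int(n)
    return records


def indication_class_venn(records: dict[str, DrugGeneRecord]) -> dict[str, int]:
    """Counts of genes per combination of indication classes (Venn cells)."""
    venn: dict[str, int] = {}
    for rec in records.values():
        if not rec.indication_classes:
            continue
        key = "+".join(sorted(rec.indication_classes))
        venn[key] = venn.get(key, 0) + 1
    return venn


def predict_new_drug_targets(
    gene_diseases: dict[str, set],
    records: dict[str, DrugGeneRecord],
    ppi: pd.DataFrame,
    ppi_min: float = 0.9,
) -> list[DrugPrediction]:
    """Rule-based (a & b & c) candidate drug-target triples (A, B, C).

    ``gene_diseases`` maps each predicted target gene to the diseases of its
    regulating functional SNPs. ``ppi`` has columns gene_a, gene_b, score
    (undirected). Predictions are deduplicated per (A, B), listing every
    qualifying partner C. The repurposing flag marks candidates that already
    carry a drug with an indication other than B.
    """
    strong: dict[str, set] = {}
    for row in ppi.itertuples(index=False):
        if row.score > ppi_min:
            strong.setdefault(row.gene_a, set()).add(row.gene_b)
            strong.setdefault(row.gene_b, set()).add(row.gene_a)
    # C candidates: drug-target genes with an autoimmune indication B
    autoimmune_of: dict[str, set] = {}
    for gene, rec in records.items():
        diseases = {ind for ind, cls in rec.indications if cls == "autoimmune"}
        if diseases:
            autoimmune_of[gene] = diseases
    found: dict[tuple[str, str], set] = {}
    for a, a_diseases in gene_diseases.items():
        rec_a = records.get(a)
        if rec_a is None or not (rec_a.known_drug_target or rec_a.druggable):
            continue  # rule (c)
        for c in strong.get(a, set()):  # rule (a)
            if c == a:
                continue
            for b in autoimmune_of.get(c, set()):
                # rule (b): both A and C regulated for disease B
                if b in a_diseases and b in gene_diseases.get(c, set()):
                    found.setdefault((a, b), set()).add(c)
    predictions = []
    for (a, b), partners in sorted(found.items()):
        rec_a = records[a]
        other_indications = {ind for ind, _cls in rec_a.indications if ind != b}
        predictions.append(
            DrugPrediction(
                candidate_gene=a,
                disease=b,
                partner_genes=tuple(sorted(partners)),
                repurposing_flag=bool(other_indications),
            )
        )
    return predictions
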