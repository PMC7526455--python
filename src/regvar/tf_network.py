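"""TF enrichment among functional SNPs and regulatory target assignment.

TFs whose allele-specific binding motifs are over-represented among functional
SNPs with predicted target genes (versus all positive SNPs; Fisher's exact
test, FC > 1, Bonferroni across tested TFs) are treated as candidate
regulators. Each enriched TF inherits the predicted targets of its bound
SNPs: a *local* edge when the SNP-gene pair is local, a *distal* edge when the
pair acts through chromatin contacts, and an *indirect* edge when the TF
directly targets the gene encoding another enriched TF, whose own direct
targets are then reachable in one hop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import ContingencyTable, association_test_2x2, fold_change

logger = logging.getLogger(__name__)


@dataclass
class TfEnrichment:
    tf_name: str
    table: ContingencyTable
    fc: float
    p: float
    p_adj: float
    enriched: bool


@dataclass(frozen=True)
class TfGeneEdge:
    tf_name: str
    gene_id: str
    model: str  # local | distal | indirect
    via: str  # supporting SNP id, or mediating TF for indirect edges


def enrich_tfs(
    functional_tf_calls: dict[str, set],
    positive_tf_calls: dict[str, set],
    alpha: float = 0.05,
) -> list[TfEnrichment]:
    """Fisher enrichment per TF: functional SNPs with targets vs all positives.

    Inputs map snp_id to the set of TFs with allele-specific motif calls on
    that SNP. Both dictionaries must cover their complete SNP universes (SNPs
    without calls map to empty sets). TFs annotating no SNP in either group
    are skipped; Bonferroni runs over the TFs actually tested.
    """
    n_func = len(functional_tf_calls)
    n_pos = len(positive_tf_calls)
    tfs = sorted(
        set().union(*functional_tf_calls.values(), *positive_tf_calls.values())
        if (functional_tf_calls or positive_tf_calls)
        else set()
    )
    tested = []
    for tf in tfs:
        a = sum(1 for calls in functional_tf_calls.values() if tf in calls)
        c = sum(1 for calls in positive_tf_calls.values() if tf in calls)
        if a == 0 and c == 0:
            continue
        tested.append((tf, a, c))
    n_tests = len(tested)
    out = []
    for tf, a, c in tested:
        table = ContingencyTable(a, n_func - a, c, n_pos - c)
        res = association_test_2x2(table, method="fisher")
        fc = fold_change(a, n_func, c, n_pos)
        p_adj = min(1.0, res.p_value * n_tests)
        enriched = fc > 1.0 and p_adj < alpha
        out.append(TfEnrichment(tf, table, fc, res.p_value, p_adj, enriched))
    return out


def assign_tf_targets(
    enriched_tfs: list[str],
    snp_tf_calls: dict[str, set],
    predicted_pairs: pd.DataFrame,
    tf_gene_mapping: dict[str, str],
    dedup_indirect: bool = False,
) -> list[TfGeneEdge]:
    """Direct (local/distal) and one-hop indirect TF-gene edges.

    ``predicted_pairs`` needs columns snp_id, gene_id, pair_class and is
    assumed to contain only predicted pairs. ``tf_gene_mapping`` maps TF name
    to the gene id encoding it; a TF without a mapping keeps its direct edges
    but cannot mediate indirect ones. With ``dedup_indirect`` an indirect edge
    to a gene the TF already reaches directly is suppressed.
    """
    enriched = [tf.upper() for tf in enriched_tfs]
    pairs_by_snp: dict[str, list[tuple[str, str]]] = {}
    for row in predicted_pairs.itertuples(index=False):
        pairs_by_snp.setdefault(row.snp_id, []).append((row.gene_id, row.pair_class))
    edges: set[TfGeneEdge] = set()
    direct_targets: dict[str, set] = {tf: set() for tf in enriched}
    for tf in enriched:
        for snp_id, calls in snp_tf_calls.items():
            if tf not in {c.upper() for c in calls}:
                continue
            for gene_id, pair_class in pairs_by_snp.get(snp_id, []):
                edges.add(TfGeneEdge(tf, gene_id, pair_class, via=snp_id))
                direct_targets[tf].add(gene_id)
    gene_to_tf = {}
    for tf in enriched:
        gene = tf_gene_mapping.get(tf) or tf_gene_mapping.get(tf.upper())
        if gene is None:
            logger.info("TF %s has no gene mapping; cannot seed indirect edges", tf)
        else:
            gene_to_tf[gene] = tf
    for tf in enriched:
        for gene_id in direct_targets[tf]:
            mediator = gene_to_tf.get(gene_id)
            if mediator is None or mediator == tf:
                continue
            for target in direct_targets[mediator]:
                if dedup_indirect and target in direct_targets[tf]:
                    continue
                edges.add(TfGeneEdge(tf, target, "indirect", via=mediator))
    return sorted(edges, key=lambda e: (e.tf_name, e.gene_id, e.model, e.via))


def shared_target_matrix(
    edges: list[TfGeneEdge],
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise shared-target counts and a greedy covering TF subset.

    The cover is built by repeatedly taking the TF covering the most
    still-uncovered targets (ties broken by TF name), until every target of
    every TF is covered.
    """
    targets: dict[str, set] = {}
    for edge in edges:
        targets.setdefault(edge.tf_name, set()).add(edge.gene_id)
    tfs = sorted(targets)
    matrix = pd.DataFrame(
        [[len(targets[t1] & targets[t2]) for t2 in tfs] for t1 in tfs],
        index=tfs,
        columns=tfs,
        dtype=int,
    )
    uncovered = set().union(*targets.values()) if targets else set()
    cover: list[str] = []
    remaining = dict(targets)
    while uncovered:
        best_tf = min(
            remaining, key=lambda tf: (-len(remaining[tf] & uncovered), tf)
        )
        gained = remaining[best_tf] & uncovered
        if not gained:
            break
        cover.append(best_tf)
        uncovered -= gained
        del remaining[best_tf]
    return matrix, cover
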