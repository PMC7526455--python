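"""Colocalization (ABF and PICS) and multi-evidence target-gene prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from regvar.coloc import coloc_abf, pics_coloc, pics_probabilities
from regvar.core import GeneModel, promoter_windows
from regvar.fixtures import generate_coloc_scenario
from regvar.target_genes import (
    filter_cis_qtl,
    interaction_support,
    is_local_pair,
    predict_target_genes,
)


def _contacts(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "dataset_id", "method"],
    )


class TestColocAbf:
    def test_identical_strong_signal_colocalizes(self):
        gwas, qtl = generate_coloc_scenario("shared", n=5000, effect=0.5, snps=100, seed=3)
        res = coloc_abf(gwas, qtl)
        assert res.pp4 > 0.8 and res.colocalized
        assert math.isclose(res.pp.sum(), 1.0, abs_tol=1e-6)

    def test_flat_signals_favor_pp0(self, rng):
        se = 1 / math.sqrt(1000)
        z = rng.uniform(-0.9, 0.9, size=50)
        gwas = pd.DataFrame({"snp_id": range(50), "beta": z * se, "se": se})
        qtl = pd.DataFrame({"snp_id": range(50), "beta": z[::-1] * se, "se": se})
        res = coloc_abf(gwas, qtl)
        assert res.pp.argmax() == 0

    def test_swapping_traits_exchanges_pp1_pp2(self):
        gwas, qtl = generate_coloc_scenario("distinct", n=2000, effect=0.3, snps=60, seed=9)
        a = coloc_abf(gwas, qtl)
        b = coloc_abf(qtl, gwas)
        assert a.pp[3] == pytest.approx(b.pp[3], abs=1e-9)
        assert a.pp[4] == pytest.approx(b.pp[4], abs=1e-9)
        assert a.pp[1] == pytest.approx(b.pp[2], abs=1e-9)
        assert a.pp[2] == pytest.approx(b.pp[1], abs=1e-9)

    def test_pp4_monotone_in_p12(self):
        gwas, qtl = generate_coloc_scenario("shared", n=2000, effect=0.2, snps=60, seed=4)
        pp4s = [coloc_abf(gwas, qtl, p12=p12).pp4 for p12 in (1e-7, 1e-6, 1e-5, 1e-4)]
        assert all(x <= y + 1e-12 for x, y in zip(pp4s, pp4s[1:]))

    def test_too_few_shared_snps_rejected(self):
        one = pd.DataFrame({"snp_id": ["a"], "beta": [0.1], "se": [0.01]})
        with pytest.raises(ValueError, match="shared SNPs"):
            coloc_abf(one, one.assign(snp_id=["b"]))

    def test_pvalue_only_route_agrees_with_beta_se(self):
        gwas, qtl = generate_coloc_scenario("shared", n=5000, effect=0.5, snps=60, seed=11)
        from scipy import stats as sps

        z = gwas.beta / gwas.se
        gwas_p = pd.DataFrame(
            {
                "snp_id": gwas.snp_id,
                "p": 2 * sps.norm.sf(abs(z)),
                "n": 5000,
                "freq": 0.5,
            }
        )
        res_bs = coloc_abf(gwas, qtl, gwas_type="quant")
        res_p = coloc_abf(gwas_p, qtl, gwas_type="quant")
        assert res_p.pp.argmax() == res_bs.pp.argmax() == 4


class TestPics:
    def test_single_snp_certain(self):
        ps = pics_probabilities("lead", 8.0, {"lead": 1.0})
        assert ps.probabilities["lead"] == 1.0 and ps.credible_set == {"lead"}

    def test_perfect_proxies_share_equally(self):
        ps = pics_probabilities("lead", 8.0, {"lead": 1.0, "proxy": 1.0})
        assert ps.probabilities["lead"] == pytest.approx(0.5)
        assert ps.probabilities["proxy"] == pytest.approx(0.5)

    def test_probability_monotone_in_r2(self):
        rs = np.linspace(0.0, 0.95, 12)
        ps = pics_probabilities("lead", 10.0, {f"s{i}": float(r) for i, r in enumerate(rs)})
        ordered = [ps.probabilities[f"s{i}"] for i in range(len(rs))]
        assert all(a <= b + 1e-15 for a, b in zip(ordered, ordered[1:]))

    def test_credible_set_reaches_mass(self):
        ps = pics_probabilities(
            "lead", 9.0, {"lead": 1.0, "a": 0.9, "b": 0.5, "c": 0.1}
        )
        assert sum(ps.probabilities[s] for s in ps.credible_set) >= 0.95

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pics_probabilities("lead", 0.0, {"lead": 1.0})
        with pytest.raises(ValueError):
            pics_probabilities("lead", 5.0, {"lead": 1.0, "x": 1.5})


class TestPicsColoc:
    def test_identical_point_masses_colocalize(self):
        g = pics_probabilities("s1", 8.0, {"s1": 1.0})
        assert pics_coloc(g, g).pp4 == pytest.approx(1.0)

    def test_distinct_point_masses_favor_pp3(self):
        g = pics_probabilities("s1", 8.0, {"s1": 1.0, "s2": 0.0})
        q = pics_probabilities("s2", 8.0, {"s2": 1.0, "s1": 0.0})
        res = pics_coloc(g, q)
        assert res.pp.argmax() == 3 and res.pp4 < 0.2

    def test_disjoint_universes_warn_and_zero_pp4(self, caplog):
        g = pics_probabilities("s1", 8.0, {"s1": 1.0})
        q = pics_probabilities("s9", 8.0, {"s9": 1.0})
        with caplog.at_level("WARNING"):
            res = pics_coloc(g, q)
        assert res.pp4 == 0.0
        assert any("disjoint" in r.message for r in caplog.records)

    def test_rank_concordance_with_abf(self):
        """PICS-based and ABF coloc agree on shared-vs-distinct labels."""
        agree = 0
        for i, kind in enumerate(["shared", "distinct"] * 10):
            gwas, qtl = generate_coloc_scenario(kind, n=5000, effect=0.5, snps=60, seed=100 + i)
            abf = coloc_abf(gwas, qtl)
            from scipy import stats as sps

            def pics_of(df):
                z = (df.beta / df.se).to_numpy()
                lead = int(np.argmax(np.abs(z)))
                logp = -sps.norm.logsf(abs(z[lead])) / math.log(10)
                # LD proxy: correlation of z profiles within the scenario blocks
                r = {
                    str(s): float(np.clip(z[j] / z[lead], -1, 1))
                    for j, s in enumerate(df.snp_id)
                }
                r[str(df.snp_id.iloc[lead])] = 1.0
                return pics_probabilities(str(df.snp_id.iloc[lead]), float(logp), r)

            pic = pics_coloc(pics_of(gwas), pics_of(qtl))
            abf_label = "shared" if abf.pp4 > abf.pp[3] else "distinct"
            pics_label = "shared" if pic.pp4 > pic.pp[3] else "distinct"
            agree += abf_label == pics_label
        assert agree >= 16  # >= 80% concordance over 20 simulated loci


class TestCisQtl:
    def _assocs(self):
        return pd.DataFrame(
            {
                "snp_id": ["s1", "s1", "s2", "s3"],
                "gene_id": ["g1", "g1", "g2", "gX"],
                "dataset_id": ["d1", "d2", "d1", "d1"],
                "p": [1e-8, 1e-6, 1e-7, 1e-9],
                "fdr": [0.01, 0.02, 0.01, 0.001],
            }
        )

    def test_dataset_count_validation(self):
        genes = {
            "g1": GeneModel("g1", "g1", "chr1", "+", [1000]),
            "g2": GeneModel("g2", "g2", "chr1", "+", [2000]),
        }
        sig, counts = filter_cis_qtl(self._assocs(), genes)
        counts = counts.set_index(["snp_id", "gene_id"])
        assert counts.loc[("s1", "g1"), "validated"]
        assert not counts.loc[("s2", "g2"), "validated"]
        assert ("s3", "gX") not in counts.index  # no gene model


class TestInteractionSupport:
    def test_cross_anchor_rule(self):
        genes = [GeneModel("g1", "g1", "chr1", "+", [100_000])]
        by_gene = {"g1": promoter_windows(genes)}
        support = _contacts(
            [("chr1", 49_000, 51_000, "chr1", 99_000, 101_000, "d1", "hic")]
        )
        assert interaction_support("chr1", 50_000, "g1", support, by_gene) == 1
        same_anchor = _contacts(
            [("chr1", 49_000, 101_000, "chr1", 500_000, 501_000, "d1", "hic")]
        )
        assert interaction_support("chr1", 50_000, "g1", same_anchor, by_gene) == 0

    def test_trans_pair_never_counts(self):
        genes = [GeneModel("g1", "g1", "chr2", "+", [100_000])]
        by_gene = {"g1": promoter_windows(genes)}
        contacts = _contacts(
            [("chr1", 49_000, 51_000, "chr2", 99_000, 101_000, "d1", "hic")]
        )
        # SNP on chr2 not in anchor1 (chr1); promoter overlap alone is not enough
        assert interaction_support("chr2", 50_000, "g1", contacts, by_gene) == 0
        # but the legitimate orientation still works
        assert interaction_support("chr1", 50_000, "g1", contacts, by_gene) == 1

    def test_counts_match_bruteforce(self, rng):
        genes = [
            GeneModel(f"g{i}", f"g{i}", "chr1", "+", [int(p)])
            for i, p in enumerate(rng.integers(10_000, 500_000, size=10))
        ]
        by_gene = {g.gene_id: promoter_windows([g]) for g in genes}
        rows = []
        for _ in range(60):
            a = int(rng.integers(0, 500_000))
            b = int(rng.integers(0, 500_000))
            rows.append(
                ("chr1", a, a + 4000, "chr1", b, b + 4000, f"d{rng.integers(3)}", "hic")
            )
        contacts = _contacts(rows)
        for _ in range(20):
            pos = int(rng.integers(1, 500_000))
            for g in genes:
                got = interaction_support("chr1", pos, g.gene_id, contacts, by_gene)
                brute = set()
                for r in rows:
                    for sa, se_, pa, pe, ds in (
                        (r[1], r[2], r[4], r[5], r[6]),
                        (r[4], r[5], r[1], r[2], r[6]),
                    ):
                        snp_in = sa <= pos - 1 < se_
                        prom = any(
                            iv.start < pe and pa < iv.end for iv in by_gene[g.gene_id]
                        )
                        if snp_in and prom:
                            brute.add(ds)
                assert got == len(brute)


class TestPredictTargetGenes:
    def _setup(self):
        genes = [
            GeneModel("gL", "gL", "chr1", "+", [10_000]),
            GeneModel("gD", "gD", "chr1", "+", [500_000]),
        ]
        by_gene = {g.gene_id: promoter_windows([g]) for g in genes}
        positions = {"sL": ("chr1", 10_200), "sD": ("chr1", 200_000)}
        counts = pd.DataFrame(
            {
                "snp_id": ["sL", "sD"],
                "gene_id": ["gL", "gD"],
                "qtl_dataset_count": [2, 2],
                "validated": [True, True],
            }
        )
        contacts = _contacts(
            [
                ("chr1", 199_000, 201_000, "chr1", 499_000, 501_000, "d1", "hic"),
                ("chr1", 199_000, 201_000, "chr1", 499_000, 501_000, "d2", "hic"),
            ]
        )
        pp4 = {"gL": 0.95, "gD": 0.95}
        return positions, counts, contacts, pp4, by_gene

    def test_local_pair_needs_no_interaction(self):
        positions, counts, contacts, pp4, by_gene = self._setup()
        pairs, gene_table = predict_target_genes(
            {"sL", "sD"}, positions, counts, contacts, pp4, by_gene
        )
        status = {(p.snp_id, p.gene_id): p.predicted for p in pairs}
        assert status[("sL", "gL")] and status[("sD", "gD")]
        classes = dict(zip(gene_table.gene_id, gene_table.gene_class))
        assert classes == {"gL": "local", "gD": "distal"}

    def test_distal_pair_requires_two_interaction_datasets(self):
        positions, counts, contacts, pp4, by_gene = self._setup()
        pairs, _ = predict_target_genes(
            {"sL", "sD"}, positions, counts, contacts.iloc[:1], pp4, by_gene
        )
        status = {(p.snp_id, p.gene_id): p.predicted for p in pairs}
        assert status[("sL", "gL")] and not status[("sD", "gD")]

    def test_removing_any_evidence_only_shrinks(self):
        """Monotone conjunction: dropping an evidence table cannot add pairs."""
        positions, counts, contacts, pp4, by_gene = self._setup()
        full, _ = predict_target_genes(
            {"sL", "sD"}, positions, counts, contacts, pp4, by_gene
        )
        base = {(p.snp_id, p.gene_id) for p in full if p.predicted}
        for weakened in (
            predict_target_genes(set(), positions, counts, contacts, pp4, by_gene),
            predict_target_genes({"sL", "sD"}, positions, counts, contacts.iloc[:0], pp4, by_gene),
            predict_target_genes({"sL", "sD"}, positions, counts, contacts, {}, by_gene),
        ):
            got = {(p.snp_id, p.gene_id) for p in weakened[0] if p.predicted}
            assert got <= base

    def test_fixture_decoys_excluded(self, pipeline_run):
        _, out, truth, _ = pipeline_run
        pairs = pd.read_csv(out / "pairs.tsv", sep="\t")
        predicted = {
            (r.snp_id, r.gene_id, r.pair_class)
            for r in pairs[pairs.predicted].itertuples(index=False)
        }
        planted = {(d["snp"], d["gene"], d["class"]) for d in truth.snp_gene_pairs}
        assert predicted == planted

    def test_local_pair_boundary(self):
        genes = [GeneModel("g", "g", "chr1", "+", [10_000])]
        by_gene = {"g": promoter_windows(genes)}
        assert is_local_pair("chr1", 11_000, "g", by_gene)
        assert not is_local_pair("chr1", 11_002, "g", by_gene)
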