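"""Interval overlap, 2x2 statistics, fold change, and p-value adjustment."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from regvar.core import (
    ContingencyTable,
    GeneModel,
    GenomicInterval,
    SnpRecord,
    adjust_pvalues,
    association_test_2x2,
    fisher_exact_pvalues,
    fold_change,
    overlap_annotate,
    promoter_windows,
)


class TestOverlapAnnotate:
    @pytest.mark.parametrize(
        "pos,start,end,expect",
        [
            (100, 99, 100, True),  # pos-1 = 99 is the last covered base
            (100, 100, 200, False),  # half-open: interval starts after the SNP
            (100, 0, 99, False),
            (101, 100, 200, True),
            (1, 0, 1, True),
        ],
    )
    def test_boundary_convention(self, pos, start, end, expect):
        ivs = [GenomicInterval("chr1", start, end)]
        assert overlap_annotate(["chr1"], [pos], ivs)[0] == expect

    def test_matches_quadratic_scan(self, rng):
        """Sorted-event overlap equals the all-pairs brute force on random data."""
        chroms = rng.choice(["chr1", "chr2"], size=1000)
        positions = rng.integers(1, 5000, size=1000)
        ivs = [
            GenomicInterval(
                rng.choice(["chr1", "chr2"]), int(s), int(s) + int(rng.integers(1, 300))
            )
            for s in rng.integers(0, 5000, size=100)
        ]
        got = overlap_annotate(chroms, positions, ivs)
        brute = np.array(
            [
                any(
                    iv.chrom == c and iv.start <= p - 1 < iv.end
                    for iv in ivs
                )
                for c, p in zip(chroms, positions)
            ]
        )
        assert np.array_equal(got, brute)

    def test_chromosome_mismatch_warns_not_raises(self, caplog):
        ivs = [GenomicInterval("chrX", 0, 100)]
        with caplog.at_level("WARNING"):
            got = overlap_annotate(["chr1"], [50], ivs)
        assert not got.any()
        assert any("no chromosome shared" in r.message for r in caplog.records)


class TestPromoterWindows:
    def test_window_arithmetic(self):
        gene = GeneModel("G1", "G1", "chr1", "+", [5000])
        (iv,) = promoter_windows([gene], half_width=1000)
        # covers 1-based positions 4000..6000
        assert iv.contains_pos(4000) and iv.contains_pos(6000)
        assert not iv.contains_pos(3999) and not iv.contains_pos(6001)

    def test_clipped_at_zero(self):
        gene = GeneModel("G1", "G1", "chr1", "+", [400])
        (iv,) = promoter_windows([gene], half_width=1000)
        assert iv.start == 0

    def test_multiple_tss_share_gene_label(self):
        gene = GeneModel("G1", "G1", "chr1", "-", [5000, 9000])
        windows = promoter_windows([gene])
        assert len(windows) == 2 and {w.label for w in windows} == {"G1"}

    def test_half_width_bounds(self):
        gene = GeneModel("G1", "G1", "chr1", "+", [5000])
        with pytest.raises(ValueError):
            promoter_windows([gene], half_width=100)


class TestFoldChange:
    def test_equal_proportions_give_unity(self):
        assert fold_change(10, 100, 100_000, 1_000_000) == 1.0
        assert fold_change(50, 100, 25, 100) == 2.0

    def test_matches_rational_formula(self, rng):
        for _ in range(200):
            a, tp, c, tb = (int(v) + 1 for v in rng.integers(0, 1000, size=4))
            a, c = min(a, tp), min(c, tb)
            expect = Fraction(a * tb, c * tp)
            assert math.isclose(fold_change(a, tp, c, tb), float(expect), rel_tol=1e-12)

    def test_zero_background_is_infinite(self):
        assert math.isinf(fold_change(5, 10, 0, 100))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1, 10, 5, 100)


class TestAssociation2x2:
    def test_identical_proportions_chi2_zero(self):
        res = association_test_2x2(ContingencyTable(50, 50, 50, 50), "chi2")
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.method == "chi2"

    def test_fisher_small_table_equals_enumeration(self):
        res = association_test_2x2(ContingencyTable(3, 1, 1, 3), "fisher")
        # support a in 0..4 with weights C(4,a)C(4,4-a); two-sided point rule
        weights = [math.comb(4, a) * math.comb(4, 4 - a) for a in range(5)]
        total = sum(weights)
        expect = sum(w for w in weights if w <= weights[3]) / total
        assert math.isclose(res.p_value, expect, rel_tol=1e-12)

    def test_chi2_and_fisher_agree_at_large_counts(self):
        chi2 = association_test_2x2(ContingencyTable(200, 800, 100, 900), "chi2")
        fisher = association_test_2x2(ContingencyTable(200, 800, 100, 900), "fisher")
        assert chi2.method == "chi2"
        assert abs(chi2.p_value - fisher.p_value) / fisher.p_value < 0.10

    def test_zero_margin_degenerate(self):
        res = association_test_2x2(ContingencyTable(0, 0, 10, 20), "chi2")
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0

    def test_low_expected_counts_fall_back_to_fisher(self):
        res = association_test_2x2(ContingencyTable(3, 1, 1, 3), "chi2")
        assert res.method == "fisher"

    def test_chi2_matches_scipy_contingency(self, rng):
        """Pearson statistic without continuity correction (independent route)."""
        for _ in range(50):
            a, b, c, d = (int(v) + 20 for v in rng.integers(0, 500, size=4))
            res = association_test_2x2(ContingencyTable(a, b, c, d), "chi2")
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert math.isclose(res.statistic, ref.statistic, rel_tol=1e-10)
            assert math.isclose(res.p_value, ref.pvalue, rel_tol=1e-10)

    def test_fisher_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 25, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = association_test_2x2(ContingencyTable(a, b, c, d), "fisher")
            ref = sps.fisher_exact([[a, b], [c, d]]).pvalue
            assert math.isclose(res.p_value, ref, rel_tol=1e-7, abs_tol=1e-12)

    def test_fold_change_populated_on_request(self):
        res = association_test_2x2(
            ContingencyTable(50, 50, 25, 75), "fisher", with_fold_change=True
        )
        assert math.isclose(res.fold_change, 2.0)

    def test_vectorized_margin_path_consistent(self):
        n, r1, c1 = 30, 12, 9
        pvals = fisher_exact_pvalues(n, r1, c1)
        lo = max(0, c1 - (n - r1))
        for i, a in enumerate(range(lo, min(r1, c1) + 1)):
            table = ContingencyTable(a, r1 - a, c1 - a, n - r1 - (c1 - a))
            assert association_test_2x2(table, "fisher").p_value == pvals[i]


class TestAdjustPvalues:
    def test_single_p_bonferroni_identity(self):
        assert adjust_pvalues([0.01], "bonferroni")[0] == 0.01

    def test_bh_step_up_hand_computation(self):
        got = adjust_pvalues([0.01, 0.02, 0.03], "bh")
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_empty_list_passthrough(self):
        assert adjust_pvalues([], "bh").size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bonferroni_never_below_raw(self, ps):
        adj = adjust_pvalues(ps, "bonferroni")
        assert np.all(adj >= np.asarray(ps) - 1e-15) and np.all(adj <= 1.0)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    def test_bh_monotone_in_raw_order(self, ps):
        adj = adjust_pvalues(ps, "bh")
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDomainTypes:
    def test_risk_allele_must_match(self):
        with pytest.raises(ValueError):
            SnpRecord("rs1", "chr1", 100, "A", "G", risk_allele="T")

    def test_interval_requires_positive_span(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)

    def test_gene_requires_tss(self):
        with pytest.raises(ValueError):
            GeneModel("G1", "G1", "chr1", "+", [])
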