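"""PWM scanning with exact DP p-values, allele-specific calls, QTL filtering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from regvar.allelic_evidence import (
    BASES,
    Pwm,
    PwmScanner,
    call_allelic_motifs,
    filter_molecular_qtl,
    prioritize_functional_snps,
    scan_pwm,
)
from regvar.core import SnpRecord, adjust_pvalues


def enumerate_pvalues(scanner: PwmScanner):
    """Independent oracle: exhaustive k-mer enumeration of the null."""
    L = len(scanner.pwm)
    table = {}
    for kmer in itertools.product(range(4), repeat=L):
        s = int(sum(scanner.bins[i, b] for i, b in enumerate(kmer)))
        w = float(np.prod([scanner.background[b] for b in kmer]))
        table[s] = table.get(s, 0.0) + w
    return table


def oracle_p(table, score):
    return sum(w for s, w in table.items() if s >= score)


def _uniform_pwm(L):
    return Pwm("U", "db", np.full((L, 4), 0.25))


def _consensus_pwm(seq, name="M", db="db"):
    mat = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        mat[i, BASES.index(b)] = 1.0
    return Pwm(name, db, mat)


class TestPwmScanner:
    def test_uniform_pwm_scores_zero_everywhere(self):
        scanner = PwmScanner(_uniform_pwm(5))
        assert scanner.window_score_int("ACGTA") == 0
        assert scanner.pvalue_int(0) == pytest.approx(1.0)

    def test_dp_equals_enumeration_length4(self, rng):
        mat = rng.dirichlet(np.ones(4) * 0.4, size=4)
        scanner = PwmScanner(Pwm("R", "db", mat))
        table = enumerate_pvalues(scanner)
        for s in sorted(table):
            assert scanner.pvalue_int(s) == pytest.approx(oracle_p(table, s), abs=1e-10)

    def test_consensus_hit_pvalue(self):
        scanner = PwmScanner(_consensus_pwm("ACGTACGT"))
        best = scanner.window_score_int("ACGTACGT")
        assert scanner.pvalue_int(best) == pytest.approx(0.25**8, rel=1e-9)

    def test_pvalue_monotone_in_score(self, rng):
        scanner = PwmScanner(Pwm("R", "db", rng.dirichlet(np.ones(4), size=6)))
        scores = np.arange(scanner._min_sum, scanner._max_sum + 1, 50)
        ps = [scanner.pvalue_int(int(s)) for s in scores]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_windows_with_n_skipped(self):
        scanner = PwmScanner(_consensus_pwm("ACGT"))
        assert scanner.window_score_int("ACNT") is None
        hit = scanner.best_hit("NNNNN")
        assert hit is None

    def test_short_sequence_no_hit(self):
        assert scan_pwm("ACG", _consensus_pwm("ACGTA"))["+"] is None


class TestAllelicCalls:
    def _snp(self, ref, alt):
        return SnpRecord("rs1", "chr1", 500, ref_allele=ref, alt_allele=alt)

    def _flank_with_motif(self, consensus, center=20, offset_in_motif=3, width=41, seed=5):
        rng = np.random.default_rng(seed)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=width))
        start = center - offset_in_motif
        seq = seq[:start] + consensus + seq[start + len(consensus):]
        return seq

    def test_destroying_consensus_gives_loss_call(self):
        cons = "ACGTTGCA"
        flank = self._flank_with_motif(cons)
        ref = flank[20]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        pwms = [
            _consensus_pwm(cons, "TF1", "db_a"),
            _consensus_pwm(cons, "TF1", "db_b"),
        ]
        calls = call_allelic_motifs(self._snp(ref, alt), flank, pwms, {"TF1"}, center=20)
        assert len(calls) == 1
        call = calls[0]
        assert call.direction == "loss" and call.retained
        assert call.supporting_databases == {"db_a", "db_b"}

    def test_single_database_not_retained(self):
        cons = "ACGTTGCA"
        flank = self._flank_with_motif(cons)
        ref = flank[20]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        calls = call_allelic_motifs(
            self._snp(ref, alt), flank, [_consensus_pwm(cons, "TF1", "db_a")],
            {"TF1"}, center=20,
        )
        assert calls and not calls[0].retained

    def test_unexpressed_tf_not_retained(self):
        cons = "ACGTTGCA"
        flank = self._flank_with_motif(cons)
        ref = flank[20]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        pwms = [_consensus_pwm(cons, "TF1", "db_a"), _consensus_pwm(cons, "TF1", "db_b")]
        calls = call_allelic_motifs(self._snp(ref, alt), flank, pwms, set(), center=20)
        assert calls and not calls[0].retained and not calls[0].expressed_tf

    def test_reverse_complement_invariance(self):
        """The call set is unchanged when the whole locus is reverse-complemented."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        cons = "ACGTTGCA"
        flank = self._flank_with_motif(cons)
        ref = flank[20]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        pwms = [_consensus_pwm(cons, "TF1", "db_a"), _consensus_pwm(cons, "TF1", "db_b")]
        fwd = call_allelic_motifs(self._snp(ref, alt), flank, pwms, {"TF1"}, center=20)
        rc_flank = "".join(comp[b] for b in reversed(flank))
        rc_center = len(flank) - 1 - 20
        rc = call_allelic_motifs(
            self._snp(comp[ref], comp[alt]), rc_flank, pwms, {"TF1"}, center=rc_center
        )
        assert {(c.tf_name, c.direction) for c in fwd} == {
            (c.tf_name, c.direction) for c in rc
        }

    def test_gain_call_when_alt_creates_match(self):
        cons = "ACGTTGCA"
        flank = self._flank_with_motif(cons)
        ref = flank[20]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        # swap alleles: the sequence carrying `alt` now holds the consensus
        broken = flank[:20] + alt + flank[21:]
        calls = call_allelic_motifs(
            SnpRecord("rs1", "chr1", 500, ref_allele=alt, alt_allele=ref),
            broken,
            [_consensus_pwm(cons, "TF1", "a"), _consensus_pwm(cons, "TF1", "b")],
            {"TF1"},
            center=20,
        )
        assert calls and calls[0].direction == "gain"

    def test_mismatched_flank_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            calls = call_allelic_motifs(
                self._snp("A", "G"), "T" * 41, [_consensus_pwm("ACGTACGT")], None, center=20
            )
        assert calls == []


class TestMolecularQtl:
    def _table(self):
        return pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3", "s4"],
                "chrom": ["chr1"] * 4,
                "pos": [100, 200, 300, 400],
                "assay": ["hQTL", "caQTL", "dsQTL", "bQTL"],
                "cell_type": ["LCL"] * 4,
                "dataset_id": ["d1"] * 4,
                "peak_chrom": ["chr1", "chr1", "chr1", None],
                "peak_start": [50, 10_000, 250, None],
                "peak_end": [150, 10_100, 350, None],
                "p": [1e-8, 1e-9, 0.5, 1e-9],
                "fdr": [0.05, 0.001, 0.6, 0.001],
            }
        )

    def test_local_significant_kept_distal_dropped(self):
        kept, n_dropped = filter_molecular_qtl(self._table())
        assert set(kept.snp_id) == {"s1"}  # s2 distal, s3 fdr, s4 no peak
        assert n_dropped == 1

    def test_bh_recomputation_matches_precomputed(self, rng):
        df = self._table().drop(columns=["fdr"])
        df["p"] = rng.uniform(0, 1, size=len(df))
        kept, _ = filter_molecular_qtl(df, fdr_max=2.0)  # keep all local rows
        # FDR is recomputed per dataset over the rows with peak coordinates
        with_peaks = df[df.peak_chrom.notna()]
        expect = pd.Series(
            adjust_pvalues(with_peaks["p"].to_numpy(), "bh"), index=with_peaks.index
        )
        assert np.allclose(kept["fdr"].to_numpy(), expect[kept.index], atol=1e-9)


class TestPrioritize:
    def test_conjunction_rule(self):
        from regvar.allelic_evidence import AllelicMotifCall

        epi = {"s1": {"DHS"}, "s2": {"DHS", "TFBS", "histone", "HMM15"}, "s3": set()}
        calls = [
            AllelicMotifCall("s1", "TF1", "loss", {"a", "b"}, True, True),
            AllelicMotifCall("s3", "TF1", "loss", {"a", "b"}, True, True),
        ]
        out = {c.snp_id: c for c in prioritize_functional_snps(["s1", "s2", "s3"], epi, calls)}
        assert out["s1"].functional  # support + motif
        assert not out["s2"].functional  # 4 categories but no allelic evidence
        assert not out["s3"].functional  # motif but no epigenetic support
        assert out["s1"].allelic_evidence == {"motif"}

    def test_fixture_recovery(self, pipeline_run):
        _, out, truth, _ = pipeline_run
        func = pd.read_csv(out / "functional.tsv", sep="\t")
        recovered = set(func[func.functional].snp_id)
        planted = set(truth.functional_snps)
        sensitivity = len(recovered & planted) / len(planted)
        assert sensitivity >= 0.9
        inert = set(func.snp_id) - planted
        false_rate = len(recovered - planted) / max(1, len(inert))
        assert false_rate <= 0.05
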