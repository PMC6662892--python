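"""Gene-element / TE priority classification, consensus matching, rank-based
differential TE targeting, and region methylation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_aln
from ospi import features as ft
from ospi.io import revcomp


def track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "name", "feat_class"])


GENE_TRACK = track([
    ("chr1", 1000, 2000, "+", "geneA_cds", "CDS"),
    ("chr1", 800, 1000, "+", "geneA_5utr", "5UTR"),
    ("chr1", 2000, 2300, "+", "geneA_3utr", "3UTR"),
    ("chr1", 2300, 4000, "+", "geneA_intron", "intron-coding"),
    ("chr1", 6000, 6500, "+", "ncA_exon", "exon-noncoding"),
    ("chr1", 6500, 8000, "+", "ncA_intron", "intron-noncoding"),
])


class TestGeneElements:
    def classify_one(self, start, end, strand="+", extra_track=None):
        use = GENE_TRACK if extra_track is None else pd.concat([GENE_TRACK, extra_track])
        aln = make_aln([("T" * (end - start), "chr1", start, end, strand, 1.0)])
        out = ft.classify_gene_elements(aln, use)
        return out["observed"].idxmax()

    def test_cds_beats_noncoding_exon(self):
        """A read inside both a CDS and a non-coding exon is CDS."""
        extra = track([("chr1", 1000, 2000, "+", "ncB_exon", "exon-noncoding")])
        assert self.classify_one(1500, 1520, extra_track=extra) == "CDS"

    def test_no_overlap_is_intergenic(self):
        assert self.classify_one(9000, 9020) == "intergenic"

    @pytest.mark.parametrize("hi_class,lo_class", [
        ("CDS", "5UTR"), ("5UTR", "3UTR"), ("3UTR", "intron-coding"),
        ("intron-coding", "exon-noncoding"), ("exon-noncoding", "intron-noncoding"),
    ])
    def test_adjacent_priority_pairs_both_orders(self, hi_class, lo_class):
        """Every adjacent class pair resolves to the earlier class however
        the track rows are ordered."""
        rows = [("chr2", 100, 400, "+", "hi", hi_class),
                ("chr2", 100, 400, "+", "lo", lo_class)]
        for order in (rows, rows[::-1]):
            aln = make_aln([("T" * 20, "chr2", 200, 220, "+", 1.0)])
            out = ft.classify_gene_elements(aln, track(order))
            assert out["observed"].idxmax() == hi_class

    def test_sense_beats_antisense_within_class(self):
        rows = track([("chr3", 100, 400, "+", "s", "CDS"),
                      ("chr3", 100, 400, "-", "a", "CDS")])
        aln = make_aln([("T" * 20, "chr3", 200, 220, "-", 1.0)])
        labels = ft._classify_rows(aln, ft._build_trees(rows), ft.GENE_ELEMENT_ORDER)
        assert labels[0] == ("CDS", "sense")

    def test_fractions_partition_to_one(self):
        rng = np.random.default_rng(4)
        rows = [("T" * 20, "chr1", int(p), int(p) + 20, "+", 1.0)
                for p in rng.integers(0, 10_000, 200)]
        out = ft.classify_gene_elements(make_aln(rows), GENE_TRACK)
        assert np.isclose(out["observed"].sum(), 1.0, atol=1e-9)

    def test_uniform_reads_have_unit_enrichment(self):
        """Random reads match their own shuffle null within 10%."""
        wide = track([
            ("chr1", 0, 5000, "+", "cds", "CDS"),
            ("chr1", 5000, 10_000, "+", "utr5", "5UTR"),
            ("chr1", 10_000, 14_000, "+", "intron", "intron-coding"),
        ])
        rng = np.random.default_rng(12)
        rows = [("T" * 20, "chr1", int(p), int(p) + 20,
                 "+" if rng.random() < 0.5 else "-", 1.0)
                for p in rng.integers(0, 19_980, 2000)]
        out = ft.classify_gene_elements(make_aln(rows), wide,
                                        chrom_sizes={"chr1": 20_000},
                                        n_shuffles=100, seed=0)
        big = out[out["observed"] >= 0.05].dropna()
        assert len(big) >= 3
        assert ((big["enrichment"] - 1).abs() <= 0.10).all()


REPEAT_TRACK = track([
    ("chr1", 10_000, 12_000, "+", "L1_A", "LINE"),
    ("chr1", 20_000, 21_000, "+", "ERV_B", "LTR"),
    ("chr1", 30_000, 30_300, "+", "Alu_C", "SINE"),
])


class TestTE:
    def classify_one(self, start, end, strand="+"):
        aln = make_aln([("T" * (end - start), "chr1", start, end, strand, 1.0)])
        out = ft.classify_te(aln, REPEAT_TRACK)
        return out["fraction"].idxmax()

    def test_antisense_line_body(self):
        aln = make_aln([("T" * 20, "chr1", 11_000, 11_020, "-", 1.0)])
        out = ft.classify_te(aln, REPEAT_TRACK)
        assert out["fraction"].idxmax() == "LINE"
        assert out.loc["LINE", "antisense"] == 1.0

    def test_500bp_upstream_of_ltr_is_fl1k(self):
        assert self.classify_one(19_480, 19_500) == "LTR-FL1k"

    def test_1500bp_away_is_fl2k(self):
        assert self.classify_one(18_480, 18_500) == "LTR-FL2k"

    def test_body_beats_flank(self):
        """A read spanning a SINE body edge counts as body, not flank."""
        assert self.classify_one(30_290, 30_310) == "SINE"

    def test_remainder_is_nonrepeat(self):
        assert self.classify_one(50_000, 50_020) == "other-nonRepeat"


class TestConsensusMatch:
    CONS = {"L1_cons": "ACGTTGCAGGATCCTAGCATGCATCGATTGCCGATACGGATC"}

    def test_exact_sense_hit(self):
        read = self.CONS["L1_cons"][5:25]
        out = ft.consensus_match(pd.DataFrame({"seq": [read]}), self.CONS)
        row = out.iloc[0]
        assert (row.offset, row.strand, row.mismatches) == (5, "sense", 0)

    def test_three_substitutions_rejected(self):
        read = list(self.CONS["L1_cons"][5:25])
        for i in (2, 8, 14):
            read[i] = "A" if read[i] != "A" else "C"
        out = ft.consensus_match(pd.DataFrame({"seq": ["".join(read)]}), self.CONS)
        assert out.empty

    def test_revcomp_with_one_substitution_is_antisense(self):
        read = list(self.CONS["L1_cons"][10:30])
        read[4] = "A" if read[4] != "A" else "C"
        out = ft.consensus_match(pd.DataFrame({"seq": [revcomp("".join(read))]}),
                                 self.CONS)
        anti = out[out.strand == "antisense"]
        assert len(anti) == 1
        assert anti.iloc[0].mismatches == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        cons = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
        reads = []
        for _ in range(10):
            i = int(rng.integers(0, 60))
            sub = list(cons[i:i + 20])
            for j in rng.integers(0, 20, int(rng.integers(0, 4))):
                sub[j] = "ACGT"[int(rng.integers(0, 4))]
            reads.append("".join(sub))
        out = ft.consensus_match(pd.DataFrame({"seq": reads}), {"c": cons})
        expected = set()
        for read in set(reads):
            for strand, q in (("sense", read), ("antisense", revcomp(read))):
                for off in range(len(cons) - len(q) + 1):
                    mm = sum(a != b for a, b in zip(cons[off:off + len(q)], q))
                    if mm <= 2:
                        expected.add((read, off, strand, mm))
        got = set(zip(out.seq, out.offset, out.strand, out.mismatches))
        assert got == expected


class TestDifferentialTE:
    def frame(self, values):
        return pd.DataFrame(values, index=[f"TE{i}" for i in range(len(values))])

    def test_identical_ranks_give_p_one(self):
        a = self.frame([[10, 11, 9, 10], [5, 6, 5, 5], [1, 1, 2, 1]])
        out = ft.differential_te(a, a.copy())
        assert (out["p"] == 1.0).all() if (out["t"] == 0).all() else True
        assert not out["significant"].any()

    def test_constant_rank_shift_is_significant(self):
        """A TE first in every os replicate and last in every piRNA
        replicate has zero rank variance and an extreme shift."""
        os_expr = self.frame([[100] * 6, [10] * 6, [1] * 6])
        pi_expr = self.frame([[1] * 6, [10] * 6, [100] * 6])
        out = ft.differential_te(os_expr, pi_expr)
        assert out.loc["TE0", "p_adj"] == 0.0
        assert out.loc["TE0", "significant"]

    def test_filter_removes_tes(self):
        a = self.frame([[10] * 4, [5] * 4, [1] * 4])
        out = ft.differential_te(a, a.copy(), te_filter=["TE1"])
        assert "TE1" not in out.index

    def test_too_few_replicates_raises(self):
        a = self.frame([[10], [5]])
        with pytest.raises(ValueError):
            ft.differential_te(a, a.copy())

    def test_null_type_one_error(self):
        """On label-permuted equal-expression data, <= 5% of TEs reach
        p < 0.05 before correction (averaged over fixed seeds)."""
        hits, total = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            expr = rng.gamma(2.0, 50.0, size=(40, 12))
            cols = rng.permutation(12)
            a = pd.DataFrame(expr[:, cols[:6]], index=[f"TE{i}" for i in range(40)])
            b = pd.DataFrame(expr[:, cols[6:]], index=[f"TE{i}" for i in range(40)])
            out = ft.differential_te(a, b)
            hits += int((out["p"] < 0.05).sum())
            total += len(out)
        assert hits / total <= 0.05


class TestRegionMethylation:
    def calls(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "context",
                                           "coverage", "methylated"])

    def test_half_methylated_region(self):
        """12 detected CpGs, 6 passing the 0.25 site rule -> ratio 0.5."""
        rows = [("chr1", 100 + i, "CpG", 10, 8 if i < 6 else 0) for i in range(12)]
        regions = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        out = ft.region_methylation(regions, self.calls(rows))
        assert out.loc[0, "CpG_detected"] == 12
        assert np.isclose(out.loc[0, "CpG_ratio"], 0.5)

    def test_nine_detected_is_na(self):
        rows = [("chr1", 100 + i, "CpG", 10, 10) for i in range(9)]
        regions = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        out = ft.region_methylation(regions, self.calls(rows))
        assert np.isnan(out.loc[0, "CpG_ratio"])

    def test_low_coverage_site_excluded(self):
        rows = ([("chr1", 100 + i, "CpG", 5, 5) for i in range(10)]
                + [("chr1", 500, "CpG", 4, 4)])
        regions = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        out = ft.region_methylation(regions, self.calls(rows))
        assert out.loc[0, "CpG_detected"] == 10

    def test_site_ratio_boundary_inclusive(self):
        """A site at exactly 25% methylation counts as methylated."""
        rows = [("chr1", 100 + i, "CpG", 8, 2) for i in range(10)]
        regions = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        out = ft.region_methylation(regions, self.calls(rows))
        assert np.isclose(out.loc[0, "CpG_ratio"], 1.0)

    def test_row_order_and_duplicates_invariant(self):
        rows = [("chr1", 100 + i, "CpG" if i % 2 else "CHH", 10, 5) for i in range(24)]
        regions = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        base = ft.region_methylation(regions, self.calls(rows))
        shuffled = self.calls(rows).sample(frac=1, random_state=0)
        doubled = pd.concat([shuffled, shuffled.head(5)])
        out = ft.region_methylation(regions, doubled)
        pd.testing.assert_frame_equal(base, out)
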