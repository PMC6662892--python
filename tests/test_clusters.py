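"""Window scan, class criteria with strict/inclusive boundaries, replicate
filtering, cluster annotation, and set overlap — with brute-force oracles
on constructed fixtures and parameter recovery on planted data."""

import numpy as np
import pandas as pd
import pytest

from conftest import jaccard, make_aln
from ospi import clusters as cl


def spread_reads(chrom, lo, hi, n, length=20, strand="+", prefix="s", count=1.0):
    """n distinct sequences with 5' positions evenly spread in [lo, hi)."""
    rows = []
    positions = np.linspace(lo, hi - length, n).astype(int)
    for i, p in enumerate(positions):
        seq = f"{prefix}{i:04d}".ljust(length, "A")[:length]
        rows.append((seq, chrom, int(p), int(p) + length, strand, count))
    return rows


class TestScan:
    def test_window_seeding_threshold(self):
        """>= 5 distinct sequences (>= 1 unique) seed a window; 4 do not."""
        five = make_aln(spread_reads("chr1", 2000, 2400, 5))
        four = make_aln(spread_reads("chr1", 2000, 2400, 4))
        assert len(cl.scan_clusters(five, chrom_sizes={"chr1": 20_000})) == 1
        assert cl.scan_clusters(four, chrom_sizes={"chr1": 20_000}) == []

    def test_requires_a_unique_sequence(self):
        rows = []
        for r in spread_reads("chr1", 2000, 2400, 6):
            rows.append(r)
            rows.append((r[0], "chr1", r[2] + 9000, r[3] + 9000, r[4], r[5]))
        aln = make_aln(rows)  # every sequence maps twice -> none unique
        assert cl.scan_clusters(aln, chrom_sizes={"chr1": 20_000}) == []

    def test_planted_cluster_recovered_and_matches_bruteforce(self):
        """A dense 3-kb block flanked by empty sequence is recovered within
        1 kb of truth, and the scan agrees with a brute-force evaluation of
        every window plus the trim rule."""
        aln = make_aln(spread_reads("chr1", 8000, 11_000, 120))
        got = cl.scan_clusters(aln, chrom_sizes={"chr1": 40_000})
        assert len(got) == 1
        chrom, start, end = got[0]
        assert abs(start - 8000) <= 1000 and abs(end - 11_000) <= 1000

        # brute-force oracle: qualifying windows, union, 1-kb edge trim
        p5 = np.sort(aln["start"].to_numpy())
        qual = [w for w in range(0, 40_000, 1000)
                if ((p5 >= w) & (p5 < w + 5000)).sum() >= 5]
        a, b = min(qual), max(qual) + 5000
        while ((p5 >= a) & (p5 < a + 1000)).sum() < 10:
            a += 1000
        while ((p5 >= b - 1000) & (p5 < b)).sum() < 10:
            b -= 1000
        inside = (p5 >= a) & (p5 < b)
        assert (start, end) == (int(p5[inside].min()),
                                int(aln["end"].to_numpy()[np.argsort(aln["start"])][inside].max()))

    def test_density_floor_monotonicity(self):
        """Raising the density floor never enlarges a cluster."""
        rows = spread_reads("chr1", 8000, 11_000, 60)
        rows += spread_reads("chr1", 11_000, 12_000, 11, prefix="t")
        aln = make_aln(rows)
        spans = {}
        for floor in (5.0, 10.0, 20.0):
            got = cl.scan_clusters(aln, chrom_sizes={"chr1": 40_000},
                                   density_floor=floor)
            spans[floor] = sum(e - s for _, s, e in got)
        assert spans[5.0] >= spans[10.0] >= spans[20.0]


def cluster_frame(n_main=90, n_other=10, length=29, u1=True, chrom="chr1",
                  lo=1000, count=1.0):
    """A synthetic candidate: n_main plus-strand and n_other minus-strand
    distinct sequences, optionally all starting with U."""
    rows = []
    for i in range(n_main + n_other):
        strand = "+" if i < n_main else "-"
        first = "T" if u1 else "G"
        seq = (first + f"{i:04d}CGCA").ljust(length, "C")[:length]
        p = lo + i * 13
        rows.append((seq, chrom, p, p + length, strand, count))
    return rows


class TestPirnaCriteria:
    def test_clean_cluster_accepted(self):
        aln = make_aln(cluster_frame())
        c = cl.classify_pirna(("chr1", 900, 3000), aln)
        assert c.accepted and c.main_strand == "+"

    def test_length_criterion_rejects(self):
        rows = cluster_frame(length=29)[:50] + cluster_frame(length=22, lo=2000)[:50]
        c = cl.classify_pirna(("chr1", 900, 4000), make_aln(rows))
        assert not c.accepted and "length_fraction" in c.reasons

    def test_exactly_75pct_main_strand_rejected(self):
        """'More than 75%' is strict: a 75.0% main-strand cluster fails."""
        aln = make_aln(cluster_frame(n_main=75, n_other=25))
        c = cl.classify_pirna(("chr1", 900, 3000), aln)
        assert np.isclose(c.frac_main_strand, 0.75)
        assert not c.accepted and "main_strand" in c.reasons

    def test_1u_or_10a_criterion(self):
        aln = make_aln(cluster_frame(u1=False))
        c = cl.classify_pirna(("chr1", 900, 3000), aln)
        assert not c.accepted and "1U_or_10A" in c.reasons


def duplex_rows(n_pairs, chrom="chr1", lo=1000, length=22, spacing=40):
    rows = []
    for i in range(n_pairs):
        s = lo + i * spacing
        plus = ("T" + f"P{i:03d}").ljust(length, "G")[:length]
        minus = ("T" + f"M{i:03d}").ljust(length, "C")[:length]
        rows.append((plus, chrom, s, s + length, "+", 1.0))
        rows.append((minus, chrom, s - 2, s + length - 2, "-", 1.0))
    return rows


class TestEndoSirnaCriteria:
    def test_duplex_cluster_accepted(self):
        aln = make_aln(duplex_rows(20) + cluster_frame(n_main=10, n_other=0,
                                                       length=22, lo=3000))
        c = cl.classify_endosirna(("chr1", 900, 4000), aln)
        assert c.accepted
        assert c.n_overhang_sequences == 40

    def test_overhang_pairs_match_exhaustive_oracle(self):
        aln = make_aln(duplex_rows(12) + cluster_frame(n_main=20, n_other=20,
                                                       length=22, lo=3000))
        sub = aln.copy()
        # oracle: all plus x minus pairs with both offsets exactly 2
        expected = set()
        plus = sub[sub.strand == "+"]
        minus = sub[sub.strand == "-"]
        for p in plus.itertuples():
            for m in minus.itertuples():
                if p.start - m.start == 2 and p.end - m.end == 2:
                    expected |= {p.seq, m.seq}
        got = cl._overhang_sequences(sub)
        assert got == expected

    def test_three_overhang_sequences_rejected(self):
        """'At least four sequences' is inclusive at 4, so 3 fails."""
        aln = make_aln(duplex_rows(1) + [
            ("T" + "X" * 21, "chr1", 2000, 2022, "+", 1.0),
            ("T" + "Y" * 21, "chr1", 2000, 2022, "-", 1.0),
        ] + cluster_frame(n_main=5, n_other=0, length=22, lo=3000))
        c = cl.classify_endosirna(("chr1", 900, 4000), aln)
        assert c.n_overhang_sequences <= 3
        assert not c.accepted

    def test_overhang_ratio_exactly_10pct_rejected(self):
        """'Higher than 10%' is strict."""
        aln = make_aln(duplex_rows(2) + cluster_frame(n_main=36, n_other=0,
                                                      length=22, lo=3000))
        c = cl.classify_endosirna(("chr1", 900, 4000), aln)
        assert np.isclose(c.frac_overhang, 0.10)
        assert not c.accepted


def pingpong_rows(n_pairs, chrom="chr1", lo=1000, length=20, spacing=50):
    rows = []
    for i in range(n_pairs):
        s = lo + i * spacing
        plus = ("T" + f"P{i:03d}").ljust(length, "G")[:length]
        minus = ("T" + f"M{i:03d}").ljust(length, "C")[:length]
        rows.append((plus, chrom, s, s + length, "+", 1.0))
        rows.append((minus, chrom, s + 10 - length, s + 10, "-", 1.0))
    return rows


class TestOsPirnaCriteria:
    def test_pingpong_cluster_accepted(self):
        aln = make_aln(pingpong_rows(10) + cluster_frame(n_main=60, n_other=5,
                                                         length=20, lo=3000))
        c = cl.classify_ospirna(("chr1", 500, 5000), aln)
        assert c.accepted
        assert c.n_pingpong_sequences >= 20

    def test_pingpong_ratio_below_1pct_rejected(self):
        """4 ping-pong sequences among ~1000 (0.4%) fail 'higher than 1%'."""
        aln = make_aln(pingpong_rows(2, spacing=60)
                       + cluster_frame(n_main=900, n_other=96, length=20,
                                       lo=4000, count=1.0))
        c = cl.classify_ospirna(("chr1", 500, 60_000), aln)
        assert c.n_pingpong_sequences == 4
        assert c.frac_pingpong < 0.01
        assert not c.accepted

    def test_low_1u10a_rejected(self):
        aln = make_aln(pingpong_rows(10) + cluster_frame(n_main=60, n_other=0,
                                                         length=20, lo=3000,
                                                         u1=False))
        c = cl.classify_ospirna(("chr1", 500, 5000), aln)
        assert not c.accepted and "1U_or_10A" in c.reasons


class TestReplicateFilter:
    def make(self, rpms):
        c = cl.Cluster("chr1", 0, 2000, "piRNA")
        c.rpm_per_replicate = rpms
        return c

    @pytest.mark.parametrize("rpms,kept", [
        ([25, 30, 21, 22, 5, 0], True),    # 4 replicates >= 20
        ([25, 30, 21, 19, 5, 0], False),   # only 3
        ([20, 20, 20, 20, 0, 0], True),    # RPM exactly 20 counts ('>= 20')
    ])
    def test_rpm_threshold(self, rpms, kept):
        out = cl.replicate_filter([self.make(rpms)])
        assert (len(out) == 1) is kept

    def test_too_few_replicates_raises(self):
        with pytest.raises(ValueError):
            cl.replicate_filter([self.make([25, 30, 21])])

    def test_min_rpm_monotonicity(self, study):
        counts = []
        for min_rpm in (5.0, 20.0, 100.0):
            n = 0
            for klass in study["called"]:
                pooled = [c for c in study["called"][klass]]
                n += len(cl.replicate_filter(pooled, min_rpm=min_rpm))
            counts.append(n)
        assert counts[0] >= counts[1] >= counts[2]


class TestRecovery:
    def test_planted_clusters_recovered(self, study):
        """>= 9/10 planted clusters per class recovered with the right class
        and Jaccard >= 0.7; nothing called on the background chromosome."""
        truth = study["result"].truth.clusters
        for klass, called in study["called"].items():
            tsub = truth[truth["name"] == klass]
            recovered = sum(
                any(c.chrom == t.chrom and jaccard((t.start, t.end),
                                                   (c.start, c.end)) >= 0.7
                    for c in called)
                for t in tsub.itertuples()
            )
            assert recovered >= 9, f"{klass}: {recovered}/10"
            assert not any(c.chrom == "chr4" for c in called)

    def test_class_disjointness(self, study):
        """Sequential prediction never assigns one sequence to two classes."""
        pooled = pd.concat(study["aln_by_rep"], ignore_index=True)
        labels = cl.annotate_by_clusters(pooled, study["called"])
        assert labels["seq"].is_unique


class TestAnnotateByClusters:
    def setup_method(self):
        self.sets = {"piRNA": [("chr1", 1000, 4000)],
                     "endo-siRNA": [("chr2", 1000, 4000)],
                     "os-piRNA": [("chr3", 1000, 4000)]}

    def label(self, seq, chrom, start):
        aln = make_aln([(seq, chrom, start, start + len(seq), "+", 1.0)])
        out = cl.annotate_by_clusters(aln, self.sets)
        return out.loc[0, "klass"]

    def test_long_read_in_pirna_cluster(self):
        assert self.label("T" * 29, "chr1", 2000) == "piRNA"

    def test_short_read_in_ospirna_cluster(self):
        assert self.label("T" * 20, "chr3", 2000) == "os-piRNA"

    def test_short_read_in_pirna_cluster_unclassified(self):
        """The length gate fails: 20-nt reads are not piRNAs."""
        assert self.label("T" * 20, "chr1", 2000) == "unclassified"


class TestSetOverlap:
    def test_identical_and_disjoint(self):
        a = [("chr1", 0, 1000), ("chr1", 5000, 6000)]
        out = cl.cluster_set_overlap({"A": a, "B": list(a)})
        assert out["membership_counts"][frozenset({"A", "B"})] == 2
        out = cl.cluster_set_overlap({"A": a, "B": [("chr2", 0, 1000)]})
        assert frozenset({"A", "B"}) not in out["membership_counts"]

    def test_three_set_counts_match_bruteforce(self):
        rng = np.random.default_rng(5)
        sets = {
            name: [("chr1", int(p), int(p) + 800)
                   for p in rng.integers(0, 50_000, 8)]
            for name in "ABC"
        }
        out = cl.cluster_set_overlap(sets)
        # oracle: merge all intervals, collect member sets
        ivs = sorted((s, e, n) for n, lst in sets.items() for _, s, e in lst)
        merged = []
        for s, e, n in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2].add(n)
            else:
                merged.append([s, e, {n}])
        expected = {}
        for _, _, members in merged:
            expected[frozenset(members)] = expected.get(frozenset(members), 0) + 1
        assert out["membership_counts"] == expected
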