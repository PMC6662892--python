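"""Sliding-window small RNA cluster discovery and classification.

The genome is scanned in 5-kb windows advanced in 1-kb steps; a window
seeds a candidate cluster when it contains at least five distinct small RNA
sequences of the candidate type, at least one of them uniquely mapped.
Overlapping qualifying windows are merged, boundaries are trimmed inward in
1-kb bins while the edge-bin density stays below 10 sequences per kb, the
interval is clipped to the read extent, and candidates no longer than
100 bp are discarded.

Candidates are then classified:

* **piRNA** (built from 25-40-nt reads): >75% of weighted read counts
  25-32 nt, >75% with the 1U-or-10A preference, >75% on the main strand.
* **endo-siRNA** (17-24-nt reads): >75% of counts 21-23 nt; at least four
  distinct sequences form a duplex with a 2-nt 3' overhang on both ends
  (plus [s,e) paired with minus [s-2,e-2)) and such sequences exceed 10%
  of the cluster's distinct sequences.
* **os-piRNA** (remaining 17-24-nt reads): >75% of counts 18-22 nt, >75%
  with 1U-or-10A, at least four distinct sequences with an opposite-strand
  partner whose 5' ends overlap by exactly 10 nt (ping-pong), and such
  sequences exceed 1% of distinct sequences.

"More than X%" thresholds are strict; "at least N" and "RPM >= 20" are
inclusive.  "Read counts" use reallocation-weighted counts; "sequences"
count distinct sequences unweighted.  Clusters are called per replicate,
accepted intervals unioned per class, and only union clusters with
RPM >= 20 in at least four replicates are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ospi.mapping import five_prime_positions

CLASS_LENGTH_RANGE = {"piRNA": (25, 32), "endo-siRNA": (21, 23), "os-piRNA": (18, 22)}
CLASS_INPUT_RANGE = {"piRNA": (25, 40), "endo-siRNA": (17, 24), "os-piRNA": (17, 24)}


@dataclass
class Cluster:
    chrom: str
    start: int
    end: int
    klass: str
    main_strand: str = "+"
    n_distinct_sequences: int = 0
    n_unique_sequences: int = 0
    weighted_count: float = 0.0
    frac_length_in_range: float = 0.0
    frac_1U_or_10A: float = 0.0
    frac_main_strand: float = 0.0
    n_overhang_sequences: int = 0
    frac_overhang: float = 0.0
    n_pingpong_sequences: int = 0
    frac_pingpong: float = 0.0
    rpm_per_replicate: list[float] = field(default_factory=list)
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def _with_p5(aln: pd.DataFrame) -> pd.DataFrame:
    if "_p5" not in aln.columns:
        aln = aln.copy()
        aln["_p5"] = five_prime_positions(aln)
    return aln


def _subset(aln: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    aln = _with_p5(aln)
    mask = (aln["chrom"] == chrom) & (aln["_p5"] >= start) & (aln["_p5"] < end)
    return aln[mask]


def filter_length(aln: pd.DataFrame, lo: int, hi: int) -> pd.DataFrame:
    lens = aln["seq"].str.len()
    return aln[(lens >= lo) & (lens <= hi)].reset_index(drop=True)


def scan_clusters(
    aln: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    window: int = 5000,
    step: int = 1000,
    min_seqs: int = 5,
    min_unique: int = 1,
    density_floor: float = 10.0,
    min_len: int = 100,
) -> list[tuple[str, int, int]]:
    """Candidate cluster intervals for one read type (length-prefiltered).

    Read membership is by 5'-end position.  ``density_floor`` is distinct
    sequences per kb; final intervals must be strictly longer than
    ``min_len`` after trimming and clipping to the read extent.
    """
    if aln.empty:
        return []
    aln = _with_p5(aln)
    candidates = []
    for chrom, sub in aln.groupby("chrom"):
        size = (chrom_sizes or {}).get(chrom, int(sub["end"].max()) + window)
        p5 = sub["_p5"].to_numpy()
        order = np.argsort(p5, kind="stable")
        p5s = p5[order]
        seqs = sub["seq"].to_numpy()[order]
        uniq = sub["unique"].to_numpy()[order]
        starts_arr = sub["start"].to_numpy()[order]
        ends_arr = sub["end"].to_numpy()[order]

        def distinct_in(a: int, b: int, need_unique: bool = False):
            lo = np.searchsorted(p5s, a, side="left")
            hi = np.searchsorted(p5s, b, side="left")
            if hi <= lo:
                return 0, 0
            block = seqs[lo:hi]
            n = len(set(block))
            nu = len(set(block[uniq[lo:hi]])) if need_unique else 0
            return n, nu

        # seed qualifying windows and merge overlaps
        merged: list[list[int]] = []
        for w in range(0, max(size - window, 0) + step, step):
            n, nu = distinct_in(w, w + window, need_unique=True)
            if n >= min_seqs and nu >= min_unique:
                if merged and w <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], w + window)
                else:
                    merged.append([w, w + window])

        for a, b in merged:
            # trim 1-kb edge bins while below the density floor; the density
            # rule sets boundaries, not existence, so the last read-bearing
            # bin is never removed (a seeded window always yields a candidate)
            changed = True
            while changed and b - a > 0:
                changed = False
                nb = min(a + 1000, b)
                if (distinct_in(a, nb)[0] / (nb - a) * 1000 < density_floor
                        and distinct_in(nb, b)[0] > 0):
                    a, changed = nb, True
                pb = max(b - 1000, a)
                if (b - a > 0
                        and distinct_in(pb, b)[0] / (b - pb) * 1000 < density_floor
                        and distinct_in(a, pb)[0] > 0):
                    b, changed = pb, True
            lo = np.searchsorted(p5s, a, side="left")
            hi = np.searchsorted(p5s, b, side="left")
            if hi <= lo:
                continue
            ext_start = int(starts_arr[lo:hi].min())
            ext_end = int(ends_arr[lo:hi].max())
            if ext_end - ext_start > min_len:
                candidates.append((chrom, ext_start, ext_end))
    return candidates


# --- per-cluster statistics ------------------------------------------------

def _has_1u_or_10a(seq: str) -> bool:
    return seq[0] == "T" or (len(seq) >= 10 and seq[9] == "A")


def _base_stats(cluster: Cluster, sub: pd.DataFrame, length_range: tuple[int, int]) -> None:
    w = sub["wcount"].to_numpy(float)
    total = w.sum()
    cluster.weighted_count = float(total)
    cluster.n_distinct_sequences = sub["seq"].nunique()
    cluster.n_unique_sequences = sub.loc[sub["unique"], "seq"].nunique()
    if total <= 0:
        return
    lens = sub["seq"].str.len().to_numpy()
    lo, hi = length_range
    cluster.frac_length_in_range = float(w[(lens >= lo) & (lens <= hi)].sum() / total)
    bias = sub["seq"].map(_has_1u_or_10a).to_numpy(bool)
    cluster.frac_1U_or_10A = float(w[bias].sum() / total)
    plus = float(w[sub["strand"].to_numpy() == "+"].sum())
    minus = float(total - plus)
    cluster.main_strand = "+" if plus >= minus else "-"
    cluster.frac_main_strand = float(max(plus, minus) / total)


def _overhang_sequences(sub: pd.DataFrame) -> set[str]:
    """Distinct sequences in >= 1 duplex with 2-nt 3' overhangs on both ends."""
    plus = sub[sub["strand"] == "+"]
    minus = sub[sub["strand"] == "-"]
    minus_ivs = {}
    for row in minus.itertuples(index=False):
        minus_ivs.setdefault((row.start, row.end), []).append(row.seq)
    out: set[str] = set()
    for row in plus.itertuples(index=False):
        partners = minus_ivs.get((row.start - 2, row.end - 2))
        if partners:
            out.add(row.seq)
            out.update(partners)
    return out


def _pingpong_sequences(sub: pd.DataFrame) -> set[str]:
    """Distinct sequences with an opposite-strand 10-nt 5'-overlap partner."""
    plus = sub[sub["strand"] == "+"]
    minus = sub[sub["strand"] == "-"]
    minus_by_end: dict[int, list] = {}
    for row in minus.itertuples(index=False):
        minus_by_end.setdefault(row.end, []).append(row)
    out: set[str] = set()
    for prow in plus.itertuples(index=False):
        for mrow in minus_by_end.get(prow.start + 10, ()):
            # both reads must cover the 10-nt overlapped span
            if mrow.start <= prow.start and mrow.end <= prow.end:
                out.add(prow.seq)
                out.add(mrow.seq)
    return out


def _classify(
    candidate: tuple[str, int, int],
    aln: pd.DataFrame,
    klass: str,
    frac_threshold: float = 0.75,
    min_signature_seqs: int = 4,
) -> Cluster:
    chrom, start, end = candidate
    cluster = Cluster(chrom=chrom, start=start, end=end, klass=klass)
    sub = _subset(aln, chrom, start, end)
    _base_stats(cluster, sub, CLASS_LENGTH_RANGE[klass])
    reasons = []
    if cluster.frac_length_in_range <= frac_threshold:
        reasons.append("length_fraction")
    if klass in ("piRNA", "os-piRNA") and cluster.frac_1U_or_10A <= frac_threshold:
        reasons.append("1U_or_10A")
    if klass == "piRNA" and cluster.frac_main_strand <= frac_threshold:
        reasons.append("main_strand")
    n_seq = max(cluster.n_distinct_sequences, 1)
    if klass == "endo-siRNA":
        seqs = _overhang_sequences(sub)
        cluster.n_overhang_sequences = len(seqs)
        cluster.frac_overhang = len(seqs) / n_seq
        if not (len(seqs) >= min_signature_seqs and cluster.frac_overhang > 0.10):
            reasons.append("overhang")
    if klass == "os-piRNA":
        seqs = _pingpong_sequences(sub)
        cluster.n_pingpong_sequences = len(seqs)
        cluster.frac_pingpong = len(seqs) / n_seq
        if not (len(seqs) >= min_signature_seqs and cluster.frac_pingpong > 0.01):
            reasons.append("pingpong")
    cluster.reasons = reasons
    cluster.accepted = not reasons
    return cluster


def classify_pirna(candidate, aln, **kw) -> Cluster:
    return _classify(candidate, aln, "piRNA", **kw)


def classify_endosirna(candidate, aln, **kw) -> Cluster:
    return _classify(candidate, aln, "endo-siRNA", **kw)


def classify_ospirna(candidate, aln, **kw) -> Cluster:
    return _classify(candidate, aln, "os-piRNA", **kw)


CLASSIFIERS = {
    "piRNA": classify_pirna,
    "endo-siRNA": classify_endosirna,
    "os-piRNA": classify_ospirna,
}


def replicate_filter(
    clusters: list[Cluster], min_rpm: float = 20.0, min_reps: int = 4
) -> list[Cluster]:
    """Keep clusters with RPM >= min_rpm (inclusive) in >= min_reps replicates."""
    out = []
    for cluster in clusters:
        rpms = cluster.rpm_per_replicate
        if len(rpms) < min_reps:
            raise ValueError(
                f"cluster has {len(rpms)} replicate RPM values; need >= {min_reps}"
            )
        if sum(r >= min_rpm for r in rpms) >= min_reps:
            out.append(cluster)
    return out


def _merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    merged: list[list] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(m) for m in merged]


def predict_class_clusters(
    aln_by_rep: list[pd.DataFrame],
    klass: str,
    totals_by_rep: list[float],
    min_rpm: float = 20.0,
    min_reps: int = 4,
    chrom_sizes: dict[str, int] | None = None,
    **scan_kw,
) -> list[Cluster]:
    """Full per-class prediction: per-replicate scan + classify, union of
    accepted intervals, per-replicate RPM on the union, replicate filter.

    ``aln_by_rep`` must already be restricted to the class's candidate
    length range; ``totals_by_rep`` are total genome-mapped weighted counts
    per replicate (all lengths) for RPM.
    """
    accepted: list[tuple[str, int, int]] = []
    for aln in aln_by_rep:
        for cand in scan_clusters(aln, chrom_sizes=chrom_sizes, **scan_kw):
            cluster = CLASSIFIERS[klass](cand, aln)
            if cluster.accepted:
                accepted.append(cluster.interval)
    union = _merge_intervals(accepted)
    pooled = pd.concat(aln_by_rep, ignore_index=True) if aln_by_rep else pd.DataFrame()
    out = []
    for chrom, start, end in union:
        cluster = CLASSIFIERS[klass]((chrom, start, end), pooled)
        cluster.accepted = True
        cluster.rpm_per_replicate = [
            float(_subset(aln, chrom, start, end)["wcount"].sum() * 1e6 / total)
            for aln, total in zip(aln_by_rep, totals_by_rep)
        ]
        out.append(cluster)
    return replicate_filter(out, min_rpm=min_rpm, min_reps=min_reps)


def _seqs_in_clusters(aln: pd.DataFrame, intervals: list[tuple[str, int, int]]) -> set[str]:
    hit: set[str] = set()
    for chrom, start, end in intervals:
        hit.update(_subset(aln, chrom, start, end)["seq"])
    return hit


def predict_all_classes(
    aln_by_rep: list[pd.DataFrame],
    totals_by_rep: list[float],
    **kw,
) -> dict[str, list[Cluster]]:
    """Sequential class prediction: piRNA (25-40-nt reads), then endo-siRNA
    (17-24 nt), then os-piRNA on the 17-24-nt reads left over after removing
    those mapping into accepted endo-siRNA clusters."""
    results: dict[str, list[Cluster]] = {}
    pi_in = [filter_length(a, *CLASS_INPUT_RANGE["piRNA"]) for a in aln_by_rep]
    results["piRNA"] = predict_class_clusters(pi_in, "piRNA", totals_by_rep, **kw)
    short_in = [filter_length(a, *CLASS_INPUT_RANGE["endo-siRNA"]) for a in aln_by_rep]
    results["endo-siRNA"] = predict_class_clusters(short_in, "endo-siRNA", totals_by_rep, **kw)
    endo_ivs = [c.interval for c in results["endo-siRNA"]]
    os_in = []
    for aln in short_in:
        drop = _seqs_in_clusters(aln, endo_ivs)
        os_in.append(aln[~aln["seq"].isin(drop)].reset_index(drop=True))
    results["os-piRNA"] = predict_class_clusters(os_in, "os-piRNA", totals_by_rep, **kw)
    return results


def annotate_by_clusters(
    aln: pd.DataFrame, cluster_sets: dict[str, list[Cluster] | list[tuple[str, int, int]]]
) -> pd.DataFrame:
    """Sequential per-sequence class assignment against retained clusters.

    piRNA: length > 24 and mapped into a piRNA cluster; then endo-siRNA
    (17-24 nt in endo-siRNA clusters); then os-piRNA (17-24 nt in os-piRNA
    clusters); remainder unclassified.  Returns [seq, klass].
    """
    def ivs(key):
        out = []
        for c in cluster_sets.get(key, []):
            out.append(c.interval if isinstance(c, Cluster) else tuple(c))
        return out

    tiers = [
        ("piRNA", ivs("piRNA"), lambda L: L > 24),
        ("endo-siRNA", ivs("endo-siRNA"), lambda L: 17 <= L <= 24),
        ("os-piRNA", ivs("os-piRNA"), lambda L: 17 <= L <= 24),
    ]
    aln = _with_p5(aln)
    labels: dict[str, str] = {}
    for klass, intervals, length_ok in tiers:
        in_clusters = _seqs_in_clusters(aln, intervals)
        for seq in in_clusters:
            if seq not in labels and length_ok(len(seq)):
                labels[seq] = klass
    rows = [(seq, labels.get(seq, "unclassified")) for seq in aln["seq"].unique()]
    return pd.DataFrame(rows, columns=["seq", "klass"])


def cluster_set_overlap(
    sets: dict[str, list[Cluster] | list[tuple[str, int, int]]],
    aln: pd.DataFrame | None = None,
) -> dict:
    """Merged-overlap comparison between cluster sets.

    All intervals are merged (strand-agnostic, >= 1-bp overlap); each merged
    region is labelled with the set names present in it, giving Venn-style
    membership counts.  With ``aln`` given, also reports per set the
    fraction of its weighted read counts falling in regions shared with at
    least one other set.
    """
    tagged = []
    for name, clusters in sets.items():
        for c in clusters:
            chrom, start, end = c.interval if isinstance(c, Cluster) else tuple(c)
            tagged.append((chrom, start, end, name))
    merged: list[list] = []  # chrom, start, end, members
    for chrom, start, end, name in sorted(tagged):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
            merged[-1][3].add(name)
        else:
            merged.append([chrom, start, end, {name}])
    membership_counts: dict[frozenset, int] = {}
    for _, _, _, members in merged:
        key = frozenset(members)
        membership_counts[key] = membership_counts.get(key, 0) + 1
    result = {"membership_counts": membership_counts, "n_merged": len(merged)}
    if aln is not None:
        shared = [(c, s, e) for c, s, e, m in merged if len(m) > 1]
        fractions = {}
        for name, clusters in sets.items():
            own = [c.interval if isinstance(c, Cluster) else tuple(c) for c in clusters]
            total = sum(_subset(aln, *iv)["wcount"].sum() for iv in own)
            in_shared = sum(
                _subset(aln, *iv)["wcount"].sum()
                for iv in own
                if any(iv[0] == c and iv[1] < e and s < iv[2] for c, s, e in shared)
            )
            fractions[name] = float(in_shared / total) if total > 0 else 0.0
        result["shared_expression_fraction"] = fractions
    return result
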