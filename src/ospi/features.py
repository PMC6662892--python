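"""Gene-element / transposable-element read classification, TE consensus
matching, differential TE targeting, and region methylation.

Gene elements are assigned hierarchically — CDS, 5'UTR, 3'UTR, intron of
protein-coding genes, exon then intron of non-coding genes — with sense
overlap beating antisense within a class and everything else intergenic; a
shuffle background (random placements preserving read length and
chromosome) turns observed class fractions into enrichments.  TEs use the
same scheme over LINE, LTR, SINE, DNA and other repeats, then their 0-1-kb
(FL1k) and 1-2-kb (FL2k) flanks.

Differential TE targeting ranks TEs by abundance within each replicate of
the two small RNA classes and compares per-TE rank vectors with a t test,
Bonferroni-corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ospi.io import revcomp
from ospi.mapping import five_prime_positions

GENE_ELEMENT_ORDER = [
    "CDS", "5UTR", "3UTR", "intron-coding", "exon-noncoding", "intron-noncoding",
]
TE_ORDER = ["LINE", "LTR", "SINE", "DNA", "other-repeat"]


def _build_trees(track: pd.DataFrame, class_col: str = "feat_class"):
    """Per (class, chrom) interval trees storing strand in the payload."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for row in track.itertuples(index=False):
        cls = getattr(row, class_col)
        trees.setdefault(cls, {}).setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.strand
        )
    return trees


def _hit(trees, cls, chrom, start, end, strand):
    """None / 'sense' / 'antisense' for the best overlap in one class."""
    tree = trees.get(cls, {}).get(chrom)
    if tree is None:
        return None
    best = None
    for iv in tree.overlap(start, end):
        if iv.data == strand:
            return "sense"
        best = "antisense"
    return best


def _classify_rows(aln, trees, order):
    labels = []
    for row in aln.itertuples(index=False):
        label = None
        for cls in order:
            orient = _hit(trees, cls, row.chrom, row.start, row.end, row.strand)
            if orient is not None:
                label = (cls, orient)
                break
        labels.append(label)
    return labels


def _fractions(aln, labels, order, rest_label):
    w = aln["wcount"].to_numpy(float)
    total = w.sum()
    out = {cls: 0.0 for cls in order}
    out[rest_label] = 0.0
    orient = {cls: {"sense": 0.0, "antisense": 0.0} for cls in order}
    for wi, label in zip(w, labels):
        if label is None:
            out[rest_label] += wi
        else:
            cls, o = label
            out[cls] += wi
            orient[cls][o] += wi
    if total > 0:
        out = {k: v / total for k, v in out.items()}
    return out, orient


def classify_gene_elements(
    aln: pd.DataFrame,
    track: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed vs shuffle-background gene-element fractions.

    ``track`` columns: chrom, start, end, strand, name, feat_class with
    feat_class in {CDS, 5UTR, 3UTR, intron-coding, exon-noncoding,
    intron-noncoding}.  Returns a frame indexed by class with columns
    [observed, background, enrichment]; background is the mean over
    ``n_shuffles`` random placements preserving read length and chromosome
    (needs ``chrom_sizes``; omit to skip the background).
    """
    trees = _build_trees(track)
    labels = _classify_rows(aln, trees, GENE_ELEMENT_ORDER)
    obs, _ = _fractions(aln, labels, GENE_ELEMENT_ORDER, "intergenic")
    out = pd.DataFrame({"observed": pd.Series(obs)})
    if chrom_sizes is not None and n_shuffles > 0:
        rng = np.random.default_rng(seed)
        acc = {k: 0.0 for k in obs}
        lengths = (aln["end"] - aln["start"]).to_numpy()
        chroms = aln["chrom"].to_numpy()
        strands = aln["strand"].to_numpy()
        for _ in range(n_shuffles):
            starts = np.array([
                rng.integers(0, max(chrom_sizes[c] - L, 1))
                for c, L in zip(chroms, lengths)
            ])
            shuffled = aln.copy()
            shuffled["start"] = starts
            shuffled["end"] = starts + lengths
            shuffled["strand"] = strands
            s_labels = _classify_rows(shuffled, trees, GENE_ELEMENT_ORDER)
            frac, _ = _fractions(shuffled, s_labels, GENE_ELEMENT_ORDER, "intergenic")
            for k, v in frac.items():
                acc[k] += v
        out["background"] = pd.Series({k: v / n_shuffles for k, v in acc.items()})
        with np.errstate(divide="ignore", invalid="ignore"):
            out["enrichment"] = out["observed"] / out["background"]
    return out


def te_flanks(repeat_track: pd.DataFrame) -> pd.DataFrame:
    """Derive FL1k (0-1 kb) and FL2k (1-2 kb) flank intervals from TE bodies."""
    rows = []
    for row in repeat_track.itertuples(index=False):
        for flank, lo, hi in (("FL1k", 0, 1000), ("FL2k", 1000, 2000)):
            for s, e in ((row.start - hi, row.start - lo), (row.end + lo, row.end + hi)):
                s = max(s, 0)
                if e > s:
                    rows.append(dict(chrom=row.chrom, start=s, end=e,
                                     strand=row.strand, name=row.name,
                                     feat_class=f"{row.feat_class}-{flank}"))
    return pd.DataFrame(rows)


def classify_te(aln: pd.DataFrame, repeat_track: pd.DataFrame) -> pd.DataFrame:
    """TE-class fractions with sense/antisense split and FL1k/FL2k tiers.

    Bodies are assigned first (LINE, LTR, SINE, DNA, other-repeat; sense
    over antisense within a class), then the ten flank classes in the order
    LINE-FL1k ... other-repeat-FL1k, LINE-FL2k ... other-repeat-FL2k;
    the remainder is other-nonRepeat.
    """
    track = pd.concat([repeat_track, te_flanks(repeat_track)], ignore_index=True)
    trees = _build_trees(track)
    order = (TE_ORDER
             + [f"{c}-FL1k" for c in TE_ORDER]
             + [f"{c}-FL2k" for c in TE_ORDER])
    labels = _classify_rows(aln, trees, order)
    frac, orient = _fractions(aln, labels, order, "other-nonRepeat")
    out = pd.DataFrame({"fraction": pd.Series(frac)})
    total = aln["wcount"].sum()
    out["sense"] = pd.Series({k: v["sense"] / total if total else 0.0 for k, v in orient.items()})
    out["antisense"] = pd.Series({k: v["antisense"] / total if total else 0.0 for k, v in orient.items()})
    return out


def consensus_match(
    reads: pd.DataFrame,
    consensus_seqs: dict[str, str],
    max_mismatch: int = 2,
) -> pd.DataFrame:
    """Hamming-distance scan of reads against TE consensus sequences.

    Every offset on both strands is tested; hits with <= ``max_mismatch``
    substitutions are reported with their strand relative to the consensus.
    Returns [seq, consensus, offset, strand, mismatches] (best hit per
    (read, consensus, strand, offset)).
    """
    rows = []
    seqs = reads["seq"].unique() if "seq" in reads.columns else list(reads)
    arrs = {name: np.frombuffer(cons.encode(), dtype="S1")
            for name, cons in consensus_seqs.items()}
    for seq in seqs:
        for strand, query in (("sense", seq), ("antisense", revcomp(seq))):
            q = np.frombuffer(query.encode(), dtype="S1")
            L = len(q)
            for name, cons in arrs.items():
                for off in range(len(cons) - L + 1):
                    mm = int((cons[off:off + L] != q).sum())
                    if mm <= max_mismatch:
                        rows.append(dict(seq=seq, consensus=name, offset=off,
                                         strand=strand, mismatches=mm))
    return pd.DataFrame(rows, columns=["seq", "consensus", "offset", "strand", "mismatches"])


def differential_te(
    os_expr_by_rep: pd.DataFrame,
    pi_expr_by_rep: pd.DataFrame,
    te_filter: list[str] | None = None,
    equal_var: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based differential TE targeting between two small RNA classes.

    Inputs are TE x replicate abundance frames (antisense expression per TE,
    each TE counted once).  Per replicate, TEs are ranked descending within
    each class; per TE a two-sample t test (Welch by default) compares the
    two rank vectors, Bonferroni-corrected over the TEs tested.  TEs named
    in ``te_filter`` (e.g. rRNA/tRNA/srpRNA/unknown-derived repeats) are
    removed first.  Zero variance in both groups yields p=1 for equal means
    and p=0 (flagged significant) otherwise.
    """
    tes = sorted(set(os_expr_by_rep.index) & set(pi_expr_by_rep.index))
    if te_filter:
        tes = [t for t in tes if t not in set(te_filter)]
    os_expr = os_expr_by_rep.loc[tes]
    pi_expr = pi_expr_by_rep.loc[tes]
    if os_expr.shape[1] < 2 or pi_expr.shape[1] < 2:
        raise ValueError("differential_te needs >= 2 replicates per class")
    os_rank = os_expr.rank(ascending=False, axis=0)
    pi_rank = pi_expr.rank(ascending=False, axis=0)
    rows = []
    m = len(tes)
    for te in tes:
        a = os_rank.loc[te].to_numpy(float)
        b = pi_rank.loc[te].to_numpy(float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t = np.inf if a.mean() > b.mean() else -np.inf
                p = 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(dict(te=te, mean_rank_os=a.mean(), mean_rank_pi=b.mean(),
                         t=float(t), p=float(p), p_adj=min(1.0, float(p) * m)))
    out = pd.DataFrame(rows).set_index("te")
    out["significant"] = out["p_adj"] <= alpha
    return out


def region_methylation(
    regions: pd.DataFrame,
    calls: pd.DataFrame,
    min_coverage: int = 5,
    min_ratio: float = 0.25,
    min_sites: int = 10,
) -> pd.DataFrame:
    """Per-region CpG / non-CpG methylation ratios from per-cytosine calls.

    ``calls`` columns: chrom, pos, context (CpG/CHG/CHH), coverage,
    methylated.  A cytosine is detected at coverage >= 5 (inclusive) and
    methylated when methylated/coverage >= 0.25; a region needs >= 10
    detected cytosines per context group or reports NA.  CHG and CHH pool
    as non-CpG.  Duplicate call rows are dropped.
    """
    calls = calls.drop_duplicates(subset=["chrom", "pos", "context"]).copy()
    calls = calls[calls["coverage"] >= min_coverage]
    calls["is_methylated"] = calls["methylated"] / calls["coverage"] >= min_ratio
    calls["group"] = np.where(calls["context"] == "CpG", "CpG", "nonCpG")
    rows = []
    for row in regions.itertuples(index=False):
        sub = calls[(calls["chrom"] == row.chrom)
                    & (calls["pos"] >= row.start) & (calls["pos"] < row.end)]
        rec = dict(chrom=row.chrom, start=row.start, end=row.end)
        for group in ("CpG", "nonCpG"):
            g = sub[sub["group"] == group]
            n = len(g)
            rec[f"{group}_detected"] = n
            rec[f"{group}_ratio"] = (
                float(g["is_methylated"].sum() / n) if n >= min_sites else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)
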