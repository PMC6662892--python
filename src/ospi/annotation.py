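"""Hierarchical annotation of mapped reads and normalization.

Perfectly mapped reads are assigned to known small RNA categories in a fixed
order — mature miRNA, isomiR, rRNA, sn/snoRNA, tRNA — and everything left
over is handed to cluster prediction.  isomiRs are mature miRNAs whose 3'
end is shifted by exactly -2, -1, +1 or +2 genome-templated nucleotides
(the 5' end is held fixed).  Reads in which a single nucleotide makes up
>= 75% of the sequence are discarded as low-complexity before mapping.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ospi.mapping import GenomeIndex

logger = logging.getLogger(__name__)

KNOWN_TIERS = ("rRNA", "sn/snoRNA", "tRNA")


def filter_low_complexity(reads: pd.DataFrame, max_frac: float = 0.75) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a read frame into (kept, removed) by the single-nucleotide rule.

    A read is removed iff its most frequent nucleotide accounts for
    >= ``max_frac`` of the sequence (inclusive boundary).
    """
    if reads.empty:
        return reads.copy(), reads.copy()
    frac = reads["seq"].map(lambda s: Counter(s).most_common(1)[0][1] / len(s))
    removed = frac >= max_frac
    return reads[~removed].reset_index(drop=True), reads[removed].reset_index(drop=True)


def _build_trees(track: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in track.itertuples(index=False):
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            row.start, row.end, row.name
        )
    return trees


def _overlap_feature(trees, chrom, start, end, strand):
    tree = trees.get((chrom, strand))
    if tree is None:
        return None
    hits = sorted(tree.overlap(start, end))
    return hits[0].data if hits else None  # first-by-coordinate tie break


def assign_known(
    aln: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    mirna_catalog: dict[str, str] | None = None,
    genome_index: GenomeIndex | None = None,
) -> pd.DataFrame:
    """Sequentially assign each mapped sequence to a known small RNA category.

    ``tracks`` maps tier name ("rRNA", "sn/snoRNA", "tRNA") to a BED-like
    frame (chrom, start, end, name, score, strand); interval tiers use
    strand-aware >= 1-bp overlap.  ``mirna_catalog`` maps mature miRNA names
    to sequences; the miRNA/isomiR tiers are sequence-based, with isomiR
    extensions validated against the genome template at the mature locus
    (needs ``genome_index``).  Returns one row per distinct sequence:
    [seq, category, feature].
    """
    mirna_catalog = mirna_catalog or {}
    by_seq = {m: name for name, m in mirna_catalog.items()}
    mature_loci: dict[str, list] = {}
    if genome_index is not None:
        for name, mature in mirna_catalog.items():
            mature_loci[name] = genome_index.find(mature)

    trees = {}
    for tier in KNOWN_TIERS:
        if tier in tracks and tracks[tier] is not None:
            trees[tier] = _build_trees(tracks[tier])
        else:
            logger.warning("no %s track provided; tier skipped", tier)

    def isomir_match(seq: str) -> str | None:
        for name, mature in mirna_catalog.items():
            # 3' trimming by 1-2 nt (trimmed bases are templated by definition)
            if len(seq) in (len(mature) - 1, len(mature) - 2) and mature.startswith(seq):
                return name
            # 3' extension by 1-2 nt, must match the genome continuation
            if len(seq) in (len(mature) + 1, len(mature) + 2) and seq.startswith(mature):
                ext = seq[len(mature):]
                for chrom, start, end, strand in mature_loci.get(name, ()):
                    if genome_index is None:
                        break
                    g = genome_index.genome[chrom]
                    if strand == "+":
                        cont = g[end:end + len(ext)]
                    else:
                        from ospi.io import revcomp
                        cont = revcomp(g[start - len(ext):start])
                    if cont == ext:
                        return name
        return None

    loci_by_seq = {
        seq: list(zip(sub["chrom"], sub["start"], sub["end"], sub["strand"]))
        for seq, sub in aln.groupby("seq")
    }
    rows = []
    for seq, loci in loci_by_seq.items():
        category, feature = "unassigned", None
        if seq in by_seq:
            category, feature = "miRNA", by_seq[seq]
        elif (hit := isomir_match(seq)) is not None:
            category, feature = "isomiR", hit
        else:
            for tier in KNOWN_TIERS:
                if tier not in trees:
                    continue
                for chrom, start, end, strand in loci:
                    feat = _overlap_feature(trees[tier], chrom, start, end, strand)
                    if feat is not None:
                        category, feature = tier, feat
                        break
                if category != "unassigned":
                    break
        rows.append(dict(seq=seq, category=category, feature=feature))
    return pd.DataFrame(rows, columns=["seq", "category", "feature"])


def rpm_normalize(counts, total_genome_mapped: float):
    """Reads per million genome-mapped reads (weighted counts)."""
    if total_genome_mapped <= 0:
        raise ValueError("total_genome_mapped must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / total_genome_mapped


def match_spikeins(reads: pd.DataFrame, spikeins: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate spike-in reads (exact sequence match) from genomic reads.

    Returns (spikein_counts with columns [name, seq, methyl3p, count],
    remaining_reads).  Spike-ins are recognized before genome mapping and
    excluded from the genome-mapped total.
    """
    spike_map = dict(zip(spikeins["seq"], spikeins["name"]))
    is_spike = reads["seq"].isin(spike_map)
    matched = reads[is_spike].copy()
    matched["name"] = matched["seq"].map(spike_map)
    counts = (
        matched.groupby("name", as_index=False).agg(seq=("seq", "first"), count=("count", "sum"))
        if not matched.empty
        else pd.DataFrame(columns=["name", "seq", "count"])
    )
    counts = spikeins.merge(counts[["name", "count"]], on="name", how="left")
    counts["count"] = counts["count"].astype(float).fillna(0.0)
    return counts, reads[~is_spike].reset_index(drop=True)


def spikein_normalize(counts, spikein_counts, scale: float = 1e6):
    """Normalize small RNA counts to the summed detected spike-in count.

    abundance = count / sum(detected spike-ins) * scale.  Raises if no
    spike-in was detected (fall back to RPM in that case).
    """
    total = float(np.asarray(spikein_counts, dtype=float).sum())
    if total <= 0:
        raise ValueError("no spike-in reads detected; use RPM normalization instead")
    return np.asarray(counts, dtype=float) / total * scale


def category_summary(aln: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Weighted count and RPM per category for one sample."""
    merged = aln.merge(assignments, on="seq", how="left")
    total = merged["wcount"].sum()
    out = merged.groupby("category")["wcount"].sum().reset_index()
    out["rpm"] = rpm_normalize(out["wcount"], total)
    return out
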