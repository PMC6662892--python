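"""Exact-match mapping of 17-40-nt reads and multimapper reallocation.

Alignments live in a pandas DataFrame with one row per (sequence, locus):
``seq, count, chrom, start, end, strand, n_loci, unique, weight, methyl3p``
plus the derived ``wcount = count * weight``.  Coordinates are 0-based
half-open; the 5' end of a minus-strand alignment is at ``end - 1``.

Multiply mapped sequences have their counts apportioned across loci in
proportion to the local density of uniquely mapped reads (summed unique
counts whose 5' ends fall within a +/-5-kb flank of each locus 5' end, both
strands pooled); if no unique read falls near any locus the count is split
equally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ospi.io import revcomp

logger = logging.getLogger(__name__)

SEED_K = 17  # minimum read length; prefix seed for the exact-match index

ALIGNMENT_COLUMNS = [
    "seq", "count", "chrom", "start", "end", "strand",
    "n_loci", "unique", "weight", "wcount", "methyl3p",
]

_VALID = frozenset("ACGT")


class GenomeIndex:
    """Prefix-seed exact matcher: 17-mer hash seeds, full-length verification."""

    def __init__(self, genome: dict[str, str], k: int = SEED_K):
        self.genome = genome
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i:i + k], []).append((chrom, i))
        self._index = index

    def find(self, seq: str) -> list[tuple[str, int, int, str]]:
        """All exact occurrences of ``seq`` on both strands, as
        (chrom, start, end, strand) with BED conventions."""
        hits = []
        L = len(seq)
        if L < self.k:
            return hits
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for chrom, i in self._index.get(query[: self.k], ()):
                if self.genome[chrom][i:i + L] == query:
                    hits.append((chrom, i, i + L, strand))
        return hits


def map_reads(
    reads: pd.DataFrame,
    genome: dict[str, str] | GenomeIndex,
    min_len: int = 17,
    max_len: int = 40,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map a collapsed read frame; returns (alignments, unmapped).

    Reads outside [min_len, max_len] are dropped; reads containing
    non-ACGT characters are skipped with a warning.  Unmapped reads are
    returned separately (they feed the 3'-tailing analysis).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    rows, unmapped = [], []
    for row in reads.itertuples(index=False):
        seq = row.seq
        if not (min_len <= len(seq) <= max_len):
            continue
        if not _VALID.issuperset(seq):
            logger.warning("skipping read with ambiguous characters: %s", seq[:20])
            continue
        hits = index.find(seq)
        if not hits:
            unmapped.append(dict(read_id=row.read_id, seq=seq, count=row.count,
                                 methyl3p=bool(row.methyl3p)))
            continue
        n = len(hits)
        for chrom, start, end, strand in hits:
            rows.append(dict(
                seq=seq, count=float(row.count), chrom=chrom, start=start,
                end=end, strand=strand, n_loci=n, unique=(n == 1),
                weight=1.0 / n, wcount=float(row.count) / n,
                methyl3p=bool(row.methyl3p), read_id=row.read_id,
            ))
    aln = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS + ["read_id"])
    unmapped_frame = pd.DataFrame(unmapped, columns=["read_id", "seq", "count", "methyl3p"])
    return aln, unmapped_frame


def five_prime_positions(aln: pd.DataFrame) -> np.ndarray:
    """Genomic 5'-end coordinate of each alignment row."""
    return np.where(aln["strand"].to_numpy() == "+",
                    aln["start"].to_numpy(),
                    aln["end"].to_numpy() - 1)


def reallocate_multimappers(aln: pd.DataFrame, flank: int = 5000) -> pd.DataFrame:
    """Reweight multimapped loci by local unique-read density.

    weight_i = U_i / sum_j U_j with U_i the summed count of uniquely mapped
    reads whose 5' ends lie within ``+/-flank`` of locus i's 5' end (both
    strands pooled).  All-zero densities fall back to an equal split.
    Unique reads keep weight 1.  Count is conserved per sequence.
    """
    if aln.empty:
        return aln.copy()
    aln = aln.reset_index(drop=True).copy()
    p5 = five_prime_positions(aln)
    aln["_p5"] = p5

    # per-chromosome sorted unique 5' positions with cumulative counts
    uniq = aln[aln["unique"]]
    density: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in uniq.groupby("chrom"):
        pos = sub["_p5"].to_numpy()
        cnt = sub["count"].to_numpy(float)
        order = np.argsort(pos, kind="stable")
        pos, cnt = pos[order], cnt[order]
        density[chrom] = (pos, np.concatenate([[0.0], np.cumsum(cnt)]))

    def local_unique(chrom: str, p: int) -> float:
        if chrom not in density:
            return 0.0
        pos, cum = density[chrom]
        lo = np.searchsorted(pos, p - flank, side="left")
        hi = np.searchsorted(pos, p + flank, side="right")
        return float(cum[hi] - cum[lo])

    weights = aln["weight"].to_numpy(float).copy()
    multi = aln[~aln["unique"]]
    # one read record may cover several loci; its weights must sum to 1,
    # so group by read identity where available (distinct read rows can
    # share a sequence, e.g. methyl-flag splits of a collapsed frame)
    group_key = "read_id" if "read_id" in aln.columns else "seq"
    for _, sub in multi.groupby(group_key, sort=False):
        u = np.array([local_unique(c, p) for c, p in zip(sub["chrom"], sub["_p5"])])
        total = u.sum()
        w = (u / total) if total > 0 else np.full(len(sub), 1.0 / len(sub))
        weights[sub.index.to_numpy()] = w
    aln["weight"] = weights
    aln["wcount"] = aln["count"] * aln["weight"]
    return aln.drop(columns="_p5")


def alignments_to_bed(aln: pd.DataFrame) -> pd.DataFrame:
    """BED6+3 view (extra columns: count, weight, n_loci)."""
    out = aln[["chrom", "start", "end"]].copy()
    out["name"] = aln["seq"]
    out["score"] = 0
    out["strand"] = aln["strand"]
    out["count"] = aln["count"]
    out["weight"] = aln["weight"]
    out["n_loci"] = aln["n_loci"]
    return out


def bed_to_alignments(bed: pd.DataFrame) -> pd.DataFrame:
    """Import externally produced BED6+3 alignments into the internal frame."""
    aln = pd.DataFrame(dict(
        seq=bed["name"], count=bed.get("count", 1.0).astype(float),
        chrom=bed["chrom"], start=bed["start"], end=bed["end"],
        strand=bed["strand"],
    ))
    n_loci = aln.groupby("seq")["seq"].transform("size")
    aln["n_loci"] = bed["n_loci"] if "n_loci" in bed else n_loci
    aln["unique"] = aln["n_loci"] == 1
    aln["weight"] = bed["weight"] if "weight" in bed else 1.0 / aln["n_loci"]
    aln["wcount"] = aln["count"] * aln["weight"]
    aln["methyl3p"] = False
    return aln[ALIGNMENT_COLUMNS]
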