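"""Nontemplated 3'-tail detection and in-silico periodate oxidation.

A read that fails perfect genome mapping is a tail candidate: removing
1-4 nt from its 3' end must leave a >= 17-nt core that maps perfectly
inside a retained os-piRNA / piRNA cluster, and the removed bases must
differ from the genomic continuation at >= 1 position (nontemplated).  The
smallest trimming that re-maps wins.  The class-level tailing ratio is
tailed counts over (perfectly mapped + tailed) counts.

In-silico NaIO4 oxidation keeps every read flagged as 3'-terminally
2'-O-methylated and drops unmethylated reads (or retains them with a
configurable survival probability), mimicking the chemical enrichment of
methylated small RNAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ospi.clusters import Cluster
from ospi.io import revcomp
from ospi.mapping import GenomeIndex

TAIL_COLUMNS = ["read_id", "seq", "count", "trimmed_length", "tail_seq",
                "tail_type", "klass", "chrom", "start", "end", "strand", "weight"]


def _intervals(cluster_sets: dict) -> list[tuple[str, str, int, int]]:
    out = []
    for klass, clusters in cluster_sets.items():
        for c in clusters:
            chrom, start, end = c.interval if isinstance(c, Cluster) else tuple(c)
            out.append((klass, chrom, start, end))
    return out


def _locus_cluster(ivs, chrom, p5):
    for klass, c, s, e in ivs:
        if c == chrom and s <= p5 < e:
            return klass
    return None


def detect_tails(
    unmapped: pd.DataFrame,
    genome_index: GenomeIndex,
    cluster_sets: dict[str, list],
    perfect_counts: dict[str, float] | None = None,
    max_trim: int = 4,
    min_core: int = 17,
) -> tuple[pd.DataFrame, dict[str, float] | None]:
    """Call 3'-tailed reads among the unmapped set.

    ``cluster_sets`` maps class name to retained clusters; a trimmed core
    must map (5' end) inside one of them.  With ``perfect_counts`` (weighted
    perfectly-mapped counts per class) the per-class tailing ratio
    tailed / (perfect + tailed) is also returned.
    """
    ivs = _intervals(cluster_sets)
    rows = []
    for row in unmapped.itertuples(index=False):
        seq = row.seq
        for k in range(1, max_trim + 1):  # smallest k wins
            core, tail = seq[:-k], seq[-k:]
            if len(core) < min_core:
                break
            hits = genome_index.find(core)
            if not hits:
                continue
            # keep hits inside a retained cluster where the tail is nontemplated
            kept = []
            for chrom, start, end, strand in hits:
                p5 = start if strand == "+" else end - 1
                klass = _locus_cluster(ivs, chrom, p5)
                if klass is None:
                    continue
                g = genome_index.genome[chrom]
                if strand == "+":
                    cont = g[end:end + k]
                else:
                    cont = revcomp(g[max(start - k, 0):start])
                if cont != tail:  # differs at >= 1 position -> nontemplated
                    kept.append((klass, chrom, start, end, strand))
            if kept:
                tail_type = "mono" if k == 1 else "oligo"
                w = 1.0 / len(kept)
                for klass, chrom, start, end, strand in kept:
                    rows.append(dict(
                        read_id=row.read_id, seq=seq, count=float(row.count),
                        trimmed_length=k, tail_seq=tail, tail_type=tail_type,
                        klass=klass, chrom=chrom, start=start, end=end,
                        strand=strand, weight=w,
                    ))
                break
            if hits:
                # core maps but outside retained clusters; larger trims would
                # only shorten the core further, still try them
                continue
    tails = pd.DataFrame(rows, columns=TAIL_COLUMNS)
    ratios = None
    if perfect_counts is not None:
        ratios = {}
        for klass, perfect in perfect_counts.items():
            tailed = float((tails.loc[tails["klass"] == klass, "count"]
                            * tails.loc[tails["klass"] == klass, "weight"]).sum())
            total = perfect + tailed
            ratios[klass] = tailed / total if total > 0 else 0.0
    return tails, ratios


def tail_composition(tails: pd.DataFrame) -> pd.DataFrame:
    """Fractions of tailed counts by tail nucleotide identity and mono/oligo.

    Identity is pure-A / pure-U / pure-C / pure-G when the whole tail is a
    single nucleotide, otherwise mixed; mono is a 1-nt tail, oligo longer.
    """
    if tails.empty:
        return pd.DataFrame(columns=["identity", "tail_type", "fraction"])
    t = tails.copy()
    t["_c"] = t["count"] * t["weight"]

    def identity(tail: str) -> str:
        if len(set(tail)) == 1:
            return {"A": "A", "T": "U", "C": "C", "G": "G"}[tail[0]]
        return "mixed"

    t["identity"] = t["tail_seq"].map(identity)
    total = t["_c"].sum()
    out = t.groupby(["identity", "tail_type"], as_index=False)["_c"].sum()
    out["fraction"] = out["_c"] / total
    return out[["identity", "tail_type", "fraction"]]


def oxidize(
    reads: pd.DataFrame,
    survival_unmethylated: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """In-silico NaIO4 oxidation: keep 3'-2'-O-methylated reads.

    Unmethylated reads survive with probability ``survival_unmethylated``
    (default 0: deterministic removal; binomial thinning of counts
    otherwise).  Requires a boolean ``methyl3p`` column.
    """
    if "methyl3p" not in reads.columns or reads["methyl3p"].isna().any():
        raise ValueError("oxidize requires per-read 3'-methylation flags")
    if survival_unmethylated <= 0.0:
        return reads[reads["methyl3p"].astype(bool)].reset_index(drop=True)
    if survival_unmethylated >= 1.0:
        return reads.copy()
    rng = np.random.default_rng(seed)
    out = reads.copy()
    unmeth = ~out["methyl3p"].astype(bool)
    thinned = rng.binomial(out.loc[unmeth, "count"].astype(int),
                           survival_unmethylated)
    out.loc[unmeth, "count"] = thinned
    return out[out["count"] > 0].reset_index(drop=True)
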