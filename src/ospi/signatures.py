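"""Ping-pong, 3'-overhang, phasing, composition and strand-bias statistics.

Geometry conventions (0-based half-open intervals, minus-strand 5' end at
``end - 1``):

* **5' overlap** between a plus-strand read ``[ps, pe)`` and a minus-strand
  read ``[ms, me)`` is ``me - ps`` — the number of bases shared at the
  5'-proximal ends — valid when positive and when both reads cover the
  overlapped span (``ms <= ps`` and ``me <= pe``).  Slicer-generated
  (ping-pong) partners overlap by exactly 10 nt.
* **3' overhang offsets** of a complementary pair are ``pe - me`` (plus-read
  3' end past the minus-read 5' end) and ``ps - ms``; a Dicer duplex has
  both equal to 2.
* **5'-to-5' phasing distance** is measured between consecutive distinct 5'
  positions on the same chromosome and strand, upstream to downstream in
  transcript orientation; each pair scores the minimum of the two position
  counts, with multimapper counts divided by their number of genomic loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ospi.mapping import five_prime_positions


@dataclass
class SignatureProfile:
    overlap_hist: pd.Series
    overhang_hist: pd.Series
    phasing_hist: pd.Series
    pos_composition: pd.DataFrame
    frac_1U: float
    frac_10A: float
    frac_1U_and_10A: float
    strand_fraction: float
    zscore_overlap10: float


def five_prime_overlap(plus: tuple, minus: tuple) -> int | None:
    """5'-end overlap length between one plus- and one minus-strand read.

    Arguments are (start, end, strand) triples.  Returns None when the
    5' ends do not overlap or either read fails to cover the span.
    """
    if plus[2] == minus[2]:
        raise ValueError("five_prime_overlap needs reads on opposite strands")
    if plus[2] != "+":
        plus, minus = minus, plus
    ps, pe, _ = plus
    ms, me, _ = minus
    d = me - ps
    if d > 0 and ms <= ps and me <= pe:
        return int(d)
    return None


def _pair_iter(aln: pd.DataFrame, max_d: int):
    """Yield (plus_row, minus_row) candidates with 5' overlap in (0, max_d]."""
    for _, sub in aln.groupby("chrom"):
        plus = sub[sub["strand"] == "+"]
        minus = sub[sub["strand"] == "-"].sort_values("end")
        if plus.empty or minus.empty:
            continue
        m_end = minus["end"].to_numpy()
        m_rows = list(minus.itertuples(index=False))
        for prow in plus.itertuples(index=False):
            lo = np.searchsorted(m_end, prow.start, side="right")
            hi = np.searchsorted(m_end, prow.start + max_d, side="right")
            for mrow in m_rows[lo:hi]:
                yield prow, mrow


def pingpong_profile(aln: pd.DataFrame, max_d: int = 30) -> tuple[pd.Series, float]:
    """5'-overlap histogram over opposite-strand pairs + z-score at 10 nt.

    Each valid pair with overlap d adds min(weighted counts) to hist[d];
    the z-score contrasts hist[10] with the mean/sd of hist[1..9, 11..20].
    """
    hist = pd.Series(0.0, index=pd.RangeIndex(1, max_d + 1, name="overlap"))
    if not aln.empty:
        for prow, mrow in _pair_iter(aln, max_d):
            d = five_prime_overlap((prow.start, prow.end, "+"), (mrow.start, mrow.end, "-"))
            if d is not None and d <= max_d:
                hist[d] += min(prow.wcount, mrow.wcount)
    background = hist[[d for d in range(1, 21) if d != 10]]
    sd = float(background.std(ddof=1))
    if sd == 0:
        z = 0.0 if hist[10] == background.mean() else float("inf")
    else:
        z = float((hist[10] - background.mean()) / sd)
    return hist, z


def overhang_profile(aln: pd.DataFrame, max_off: int = 10) -> tuple[pd.Series, float]:
    """3'-overhang offset histogram over complementary pairs + Dicer fraction.

    For each overlapping opposite-strand pair both offsets (pe - me and
    ps - ms) are recorded, weighted by min(pair weighted counts).  The
    fraction is: distinct sequences in >= 1 exact-2/2 duplex over distinct
    sequences in >= 1 complementary pair.
    """
    hist = pd.Series(0.0, index=pd.RangeIndex(-max_off, max_off + 1, name="offset"))
    paired: set[str] = set()
    dicer: set[str] = set()
    if not aln.empty:
        for _, sub in aln.groupby("chrom"):
            plus = sub[sub["strand"] == "+"]
            minus = sub[sub["strand"] == "-"].sort_values("start")
            if plus.empty or minus.empty:
                continue
            m_start = minus["start"].to_numpy()
            m_rows = list(minus.itertuples(index=False))
            max_mlen = int((minus["end"] - minus["start"]).max())
            for prow in plus.itertuples(index=False):
                # overlapping minus reads: ms < pe and me > ps
                lo = np.searchsorted(m_start, prow.start - max_mlen, side="left")
                hi = np.searchsorted(m_start, prow.end, side="left")
                for mrow in m_rows[lo:hi]:
                    if mrow.end <= prow.start:
                        continue
                    paired.add(prow.seq)
                    paired.add(mrow.seq)
                    score = min(prow.wcount, mrow.wcount)
                    o1, o2 = prow.end - mrow.end, prow.start - mrow.start
                    for off in (o1, o2):
                        if -max_off <= off <= max_off:
                            hist[off] += score
                    if o1 == 2 and o2 == 2:
                        dicer.add(prow.seq)
                        dicer.add(mrow.seq)
    frac = len(dicer) / len(paired) if paired else 0.0
    return hist, float(frac)


def phasing_profile(
    aln: pd.DataFrame, max_d: int = 80, mode: str = "adjacent"
) -> pd.Series:
    """5'-to-5' distance histogram scored by the min-count rule.

    Counts are aggregated per distinct (chrom, strand, 5' position), each
    alignment contributing count / n_loci.  ``mode='adjacent'`` pairs
    consecutive distinct positions; ``mode='all'`` pairs every position
    with every downstream position within ``max_d``.
    """
    if mode not in ("adjacent", "all"):
        raise ValueError("mode must be 'adjacent' or 'all'")
    hist = pd.Series(0.0, index=pd.RangeIndex(0, max_d + 1, name="distance"))
    if aln.empty:
        return hist
    aln = aln.copy()
    aln["_p5"] = five_prime_positions(aln)
    aln["_c"] = aln["count"] / aln["n_loci"]
    grouped = aln.groupby(["chrom", "strand", "_p5"])["_c"].sum()
    for (_, strand), sub in grouped.groupby(level=[0, 1]):
        pos = sub.index.get_level_values("_p5").to_numpy()
        cnt = sub.to_numpy()
        order = np.argsort(pos)
        pos, cnt = pos[order], cnt[order]
        if strand == "-":  # transcript direction runs right to left
            pos, cnt = pos[::-1], cnt[::-1]
        n = len(pos)
        for i in range(n - 1):
            js = range(i + 1, i + 2) if mode == "adjacent" else range(i + 1, n)
            for j in js:
                d = abs(int(pos[j]) - int(pos[i]))
                if d > max_d:
                    break
                hist[d] += min(cnt[i], cnt[j])
    return hist


def modal_distance(hist: pd.Series, min_d: int = 1) -> int:
    """Argmax of a histogram, ignoring bins below ``min_d``."""
    sub = hist[hist.index >= min_d]
    return int(sub.idxmax())


def composition_profile(
    aln: pd.DataFrame, n_positions: int = 30
) -> tuple[pd.DataFrame, float, float, float]:
    """Weighted positional nucleotide composition and 1U/10A fractions.

    Returns (pos_composition, frac_1U, frac_10A, frac_1U_and_10A).  Reads
    shorter than 10 nt are excluded from the 10A denominators.  Raises on
    an empty read set (empty-profile).
    """
    if aln.empty or aln["wcount"].sum() <= 0:
        raise ValueError("empty-profile: no reads for composition")
    w = aln["wcount"].to_numpy(float)
    seqs = aln["seq"].to_numpy()
    comp = np.zeros((n_positions, 4))
    bases = "ACGT"
    for seq, wi in zip(seqs, w):
        for i, b in enumerate(seq[:n_positions]):
            j = bases.find(b)
            if j >= 0:
                comp[i, j] += wi
    totals = comp.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, comp / totals, np.nan)
    table = pd.DataFrame(frac, columns=["A", "C", "G", "U"],
                         index=pd.RangeIndex(1, n_positions + 1, name="position"))
    # column order A C G T -> relabel T as U for reporting
    table.columns = ["A", "C", "G", "U"]
    total_w = w.sum()
    u1 = np.array([s[0] == "T" for s in seqs])
    frac_1u = float(w[u1].sum() / total_w)
    long_enough = np.array([len(s) >= 10 for s in seqs])
    w10 = w[long_enough].sum()
    a10 = np.array([len(s) >= 10 and s[9] == "A" for s in seqs])
    frac_10a = float(w[a10].sum() / w10) if w10 > 0 else 0.0
    both = u1 & a10
    frac_both = float(w[both].sum() / w10) if w10 > 0 else 0.0
    return table, frac_1u, frac_10a, frac_both


def strand_bias(aln: pd.DataFrame) -> float:
    """Fraction of weighted counts on the majority strand, in [0.5, 1]."""
    total = aln["wcount"].sum()
    if total <= 0:
        return 0.5
    plus = aln.loc[aln["strand"] == "+", "wcount"].sum()
    return float(max(plus, total - plus) / total)


def signature_profile(aln: pd.DataFrame, max_d: int = 30, phasing_max: int = 80) -> SignatureProfile:
    """Bundle all signature statistics for one read set."""
    overlap_hist, z10 = pingpong_profile(aln, max_d=max_d)
    overhang_hist, _ = overhang_profile(aln)
    phasing_hist = phasing_profile(aln, max_d=phasing_max)
    comp, f1u, f10a, fboth = composition_profile(aln)
    return SignatureProfile(
        overlap_hist=overlap_hist,
        overhang_hist=overhang_hist,
        phasing_hist=phasing_hist,
        pos_composition=comp,
        frac_1U=f1u,
        frac_10A=f10a,
        frac_1U_and_10A=fboth,
        strand_fraction=strand_bias(aln),
        zscore_overlap10=z10,
    )
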