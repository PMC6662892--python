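"""Shared fixtures: a session-scoped default study simulation (mapped and
cluster-called once, reused by recovery and acceptance tests) and small
builders for hand-constructed alignment frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ospi import clusters as cl
from ospi import simulate as sim
from ospi.mapping import ALIGNMENT_COLUMNS, GenomeIndex, map_reads, reallocate_multimappers


def make_aln(rows):
    """Build an alignment frame from (seq, chrom, start, end, strand, count)
    tuples (n_loci inferred per sequence, weight = 1/n_loci)."""
    frame = pd.DataFrame(rows, columns=["seq", "chrom", "start", "end", "strand", "count"])
    n_loci = frame.groupby("seq")["seq"].transform("size")
    frame["n_loci"] = n_loci
    frame["unique"] = n_loci == 1
    frame["weight"] = 1.0 / n_loci
    frame["wcount"] = frame["count"] * frame["weight"]
    frame["methyl3p"] = False
    return frame[ALIGNMENT_COLUMNS]


def map_replicates(result: sim.SimResult):
    """Map every replicate of a simulation; returns (aln_by_rep, totals,
    unmapped_by_rep, index)."""
    index = GenomeIndex(result.genome)
    aln_by_rep, totals, unmapped_by_rep = [], [], []
    for reads in result.reads_by_replicate:
        aln, unmapped = map_reads(reads, index)
        aln = reallocate_multimappers(aln)
        aln_by_rep.append(aln)
        totals.append(float(aln["wcount"].sum()))
        unmapped_by_rep.append(unmapped)
    return aln_by_rep, totals, unmapped_by_rep, index


@pytest.fixture(scope="session")
def study():
    """Default study simulation: 10 planted clusters per class, 6 replicates,
    one background-only chromosome; mapped and cluster-called."""
    result = sim.simulate(sim.default_study_config(seed=1, clusters_per_class=10))
    aln_by_rep, totals, unmapped_by_rep, index = map_replicates(result)
    called = cl.predict_all_classes(aln_by_rep, totals)
    return dict(result=result, aln_by_rep=aln_by_rep, totals=totals,
                unmapped_by_rep=unmapped_by_rep, index=index, called=called)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0
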