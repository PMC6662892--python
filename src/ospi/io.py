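"""File I/O for the toolkit's plain-text formats.

Genomes are FASTA; read sets are either collapsed FASTA (the read count and
the 3'-2'-O-methyl flag ride in the header as ``name_m{0|1}_x{count}``) or
expanded FASTQ; annotation tracks and clusters are BED6(+); spike-ins are a
three-column TSV.  All sequences are stored in the DNA alphabet (U -> T).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COLLAPSED_RE = re.compile(r"(?:_m(?P<m>[01]))?_x(?P<n>\d+)$")

READ_COLUMNS = ["read_id", "seq", "count", "methyl3p"]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a small RNA read set into the collapsed frame [read_id, seq, count, methyl3p].

    Collapsed FASTA headers carry ``_x<count>`` (and optionally ``_m<0|1>``
    for the 3' methyl flag); FASTQ records each count one read.  Identical
    (sequence, methyl flag) records are merged.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix in {".fastq", ".fq"} else "fasta"
    rows = []
    for rec in SeqIO.parse(str(path), fmt):
        count, methyl = 1, False
        m = _COLLAPSED_RE.search(rec.id)
        if m:
            count = int(m.group("n"))
            methyl = m.group("m") == "1"
        rows.append((rec.id, normalize_seq(str(rec.seq)), count, methyl))
    frame = pd.DataFrame(rows, columns=READ_COLUMNS)
    if frame.empty:
        return frame
    frame = (
        frame.groupby(["seq", "methyl3p"], as_index=False, sort=False)
        .agg(count=("count", "sum"), read_id=("read_id", "first"))
    )
    return frame[READ_COLUMNS]


def write_collapsed_fasta(reads: pd.DataFrame, path: str | Path) -> Path:
    """Write a read frame as collapsed FASTA with count/methyl-bearing headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, row in enumerate(reads.itertuples(index=False)):
            flag = 1 if getattr(row, "methyl3p", False) else 0
            fh.write(f">r{i}_m{flag}_x{int(row.count)}\n{row.seq}\n")
    return path


def write_fastq(reads: pd.DataFrame, path: str | Path) -> Path:
    """Expand a collapsed read frame to FASTQ (constant Q40)."""
    path = Path(path)
    with open(path, "w") as fh:
        n = 0
        for row in reads.itertuples(index=False):
            qual = "I" * len(row.seq)
            for _ in range(int(row.count)):
                fh.write(f"@r{n}\n{row.seq}\n+\n{qual}\n")
                n += 1
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame.columns = BED6_COLUMNS[: frame.shape[1]] + [
        f"extra{i}" for i in range(max(0, frame.shape[1] - 6))
    ]
    return frame


def write_bed(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in BED6_COLUMNS if c in frame.columns]
    frame.to_csv(path, sep="\t", header=False, index=False, columns=cols)
    return path


def read_spikein_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame["seq"] = frame["seq"].map(normalize_seq)
    frame["methyl3p"] = frame["methyl3p"].astype(int).astype(bool)
    return frame[["name", "seq", "methyl3p"]]


def write_spikein_tsv(spikeins: list[tuple[str, str, bool]], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(spikeins, columns=["name", "seq", "methyl3p"])
    frame["seq"] = frame["seq"].map(normalize_seq)
    frame["methyl3p"] = frame["methyl3p"].astype(int)
    frame.to_csv(path, sep="\t", index=False)
    return path
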