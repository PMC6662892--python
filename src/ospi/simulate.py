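"""Synthetic small RNA-seq data with planted ground truth.

The simulator builds a toy genome and plants read-generating loci ("clusters")
whose reads carry the statistical structure each small RNA class is defined
by:

* **piRNA** clusters: 25-32-nt reads (mode 30 nt), strong 5'-U bias, one
  dominant strand, head-to-tail phased precursor fragmentation, 3'-terminal
  2'-O-methylation on most reads.
* **endo-siRNA** clusters: 21-23-nt reads (mode 22 nt) produced largely as
  Dicer-style duplexes whose two strands leave a 2-nt 3' overhang on both
  ends, no strand preference, no 3' methylation.
* **os-piRNA** clusters: 18-22-nt reads (mode 20 nt), 1U/10A bias, one
  dominant strand, a fraction of reads generated as slicer (ping-pong)
  partners whose 5' ends overlap by exactly 10 nt, phased, and **no**
  3' methylation.
* **background**: sparse reads with no structure, for false-positive checks.

Sequence-level biases (5' U, position-10 A) are realised by pinning genome
template bases *before* read extraction, so every emitted read (minus any
nontemplated tail) matches the genome exactly at its recorded locus.
Nontemplated 3' tails are appended with each tail base rejection-sampled to
differ from the genomic continuation.  Read counts are Poisson around the
configured per-replicate expression; there is no sequencing-error or
adapter model and FASTQ qualities are constant Q40.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ospi import io as oio

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Spike-in design: six oligos, three carrying a 3'-terminal 2'-O-methyl
#: group (synthetic sequences; the design counts mirror the assay).
DEFAULT_SPIKEINS: list[tuple[str, str, bool]] = [
    ("spike-in-1", "TACGCTAGTCAGGATCCTAGTC", False),
    ("spike-in-2", "CGATCGGATGCTTACCGATGCA", False),
    ("spike-in-3", "GTCATCCAGTTACGGACTGATC", False),
    ("spike-in-1Me", "ATCGGACCTAGTTGCATCGGTA", True),
    ("spike-in-2Me", "CCTAGATCGTAGCATGGTACCG", True),
    ("spike-in-3Me", "TGGACTAGCATCGATTCCGAGT", True),
]

_CLASS_DEFAULTS: dict[str, dict] = {
    "piRNA": dict(
        length_dist={25: 0.03, 26: 0.04, 27: 0.06, 28: 0.10, 29: 0.17,
                     30: 0.35, 31: 0.15, 32: 0.10},
        u1_bias=0.85, a10_bias=0.35, strand_bias=0.9,
        pingpong_frac=0.0, overhang_frac=0.0, phased=True,
        methyl3p_frac=0.95,
    ),
    "endo-siRNA": dict(
        length_dist={21: 0.2, 22: 0.6, 23: 0.2},
        u1_bias=0.35, a10_bias=0.25, strand_bias=0.5,
        pingpong_frac=0.0, overhang_frac=0.6, phased=False,
        methyl3p_frac=0.0,
    ),
    "os-piRNA": dict(
        length_dist={18: 0.05, 19: 0.2, 20: 0.5, 21: 0.2, 22: 0.05},
        u1_bias=0.85, a10_bias=0.5, strand_bias=0.9,
        pingpong_frac=0.25, overhang_frac=0.0, phased=True,
        methyl3p_frac=0.0,
    ),
    "background": dict(
        length_dist={n: 1 / 19 for n in range(17, 36)},
        u1_bias=None, a10_bias=None, strand_bias=0.5,
        pingpong_frac=0.0, overhang_frac=0.0, phased=False,
        methyl3p_frac=0.0,
    ),
}

KLASSES = tuple(_CLASS_DEFAULTS)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class PlantedClusterSpec:
    """One read-generating locus with class-dependent defaults.

    ``None`` fields are filled from the class profile (see module docstring).
    Fractions: ``u1_bias`` / ``a10_bias`` control the realised 5'-U and
    position-10-A frequencies; ``strand_bias`` the main-strand share;
    ``pingpong_frac`` the share of reads emitted as slicer partner pairs;
    ``overhang_frac`` the share emitted as 2-nt-3'-overhang duplex pairs;
    ``expression`` is the expected read count per replicate.
    """

    chrom: str
    start: int
    end: int
    klass: str
    length_dist: dict[int, float] | None = None
    u1_bias: float | None = None
    a10_bias: float | None = None
    strand_bias: float | None = None
    pingpong_frac: float | None = None
    overhang_frac: float | None = None
    phased: bool | None = None
    expression: float = 500.0
    methyl3p_frac: float | None = None

    def __post_init__(self):
        if self.klass not in _CLASS_DEFAULTS:
            raise ConfigurationError(f"unknown cluster class {self.klass!r}")
        if self.end - self.start <= 100:
            raise ConfigurationError("cluster span must exceed 100 bp")
        defaults = _CLASS_DEFAULTS[self.klass]
        for name, value in defaults.items():
            if getattr(self, name) is None:
                setattr(self, name, value)
        total = sum(self.length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("length_dist must sum to 1")


@dataclass
class SimConfig:
    genome_length: list[int] = field(default_factory=lambda: [100_000])
    n_chromosomes: int | None = None
    cluster_specs: list[PlantedClusterSpec] = field(default_factory=list)
    n_replicates: int = 6
    spikeins: list[tuple[str, str, bool]] = field(
        default_factory=lambda: list(DEFAULT_SPIKEINS)
    )
    spikein_copies: int = 500
    seed: int = 0
    tail_prob: float = 0.0
    tail_length_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.1, 4: 0.05}
    )
    tail_nt_dist: dict[str, float] = field(
        default_factory=lambda: {"A": 0.5, "T": 0.3, "C": 0.1, "G": 0.1}
    )

    def __post_init__(self):
        if self.n_chromosomes is None:
            self.n_chromosomes = len(self.genome_length)
        if self.n_chromosomes != len(self.genome_length):
            raise ConfigurationError("n_chromosomes disagrees with genome_length")
        if any(L < 20_000 for L in self.genome_length):
            raise ConfigurationError(
                "each chromosome must be >= 20,000 bp so a 5-kb window scan is nondegenerate"
            )
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for dist in (self.tail_length_dist, self.tail_nt_dist):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigurationError("distribution must sum to 1")
        if not 0.0 <= self.tail_prob <= 1.0:
            raise ConfigurationError("tail_prob must be in [0,1]")
        seen: dict[str, list[tuple[int, int, str]]] = {}
        for spec in self.cluster_specs:
            for s, e, k in seen.get(spec.chrom, []):
                if spec.start < e and s < spec.end and k != spec.klass:
                    raise ConfigurationError(
                        f"overlapping cluster specs of different class on {spec.chrom}"
                    )
            seen.setdefault(spec.chrom, []).append((spec.start, spec.end, spec.klass))

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class TruthAnnotation:
    """Planted ground truth: cluster table and per-read provenance.

    ``clusters``: chrom, start, end, name(=klass), score(=expression), strand.
    ``reads``: one row per emitted read with its source cluster, coordinates,
    role (single / phased / pingpong_primary / pingpong_secondary /
    duplex_plus / duplex_minus), symmetric pair id, tail string and 3'
    methyl flag.
    """

    clusters: pd.DataFrame
    reads: pd.DataFrame


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    reads_by_replicate: list[pd.DataFrame]
    truth: TruthAnnotation


def generate_genome(config: SimConfig) -> dict[str, str]:
    """i.i.d. uniform-ACGT chromosomes, deterministic under ``config.seed``."""
    rng = np.random.default_rng([config.seed, 982451653 % (2**31)])
    genome = {}
    for name, length in zip(config.chrom_names, config.genome_length):
        genome[name] = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
        )
    return genome


def _sample(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist)
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


class _Planter:
    """Accumulates read coordinates and genome base pins, then extracts."""

    def __init__(self, config: SimConfig, genome: dict[str, str]):
        self.config = config
        self.genome = {c: bytearray(s, "ascii") for c, s in genome.items()}
        self.pins: dict[tuple[str, int], str] = {}
        self.site_base: dict[tuple, str] = {}
        self.rows: list[dict] = []
        self.lattices: dict[int, dict[str, list]] = {}
        self._pair_id = 0

    # --- base pinning -----------------------------------------------------
    def _pin(self, chrom: str, pos: int, base: str) -> None:
        key = (chrom, pos)
        if key not in self.pins:
            self.pins[key] = base
            self.genome[chrom][pos] = ord(base)

    def apply_pins(self, rng: np.random.Generator) -> None:
        """Pin genome template bases so reads realise their 1U / 10A draws.

        All 5'-base (1U) pins are applied before any position-10 (10A) pin:
        in dense clusters almost every base is simultaneously some read's
        5' site and another read's position 10, and the 5'-identity bias is
        the stronger class signature, so it wins contested positions.
        Within a phase the first pin wins; reads whose site base is already
        forced (by the opposite strand or an earlier phase) simply record
        the forced outcome, and free sites are drawn with a compensating
        probability so each cluster's realised fraction tracks its bias.
        """
        for role_key, phase, want in (("u1", "_u1", "T"), ("a10", "_a10", "A")):
            def site_of(r):
                if r[phase] is None:
                    return None
                strand = r["strand"]
                p5 = r["start"] if strand == "+" else r["end"] - 1
                if role_key == "u1":
                    gpos = p5
                elif r["end"] - r["start"] >= 10:
                    gpos = p5 + 9 if strand == "+" else p5 - 9
                else:
                    return None
                return (r["chrom"], strand, p5, role_key), gpos

            # read multiplicity per 5' site: decisions are made once per
            # site but weighted by how many reads share it, so the
            # *read-level* realised fraction tracks the bias even when a
            # few lattice sites carry most of the reads
            mult: dict[tuple, int] = {}
            for r in self.rows:
                loc = site_of(r)
                if loc is not None:
                    mult[loc[0]] = mult.get(loc[0], 0) + 1

            tally: dict[int, tuple[float, float]] = {}  # cluster -> (W, hits)
            for r in self.rows:
                loc = site_of(r)
                if loc is None:
                    continue
                key, gpos = loc
                if key in self.site_base:
                    continue  # site already decided and tallied
                chrom, strand = key[0], key[1]
                w = mult[key]
                seen, hits = tally.get(r["cluster"], (0.0, 0.0))
                if (chrom, gpos) in self.pins:
                    g = self.pins[(chrom, gpos)]
                    base = g if strand == "+" else g.translate(COMPLEMENT)
                else:
                    p = min(max((r[phase] * (seen + w) - hits) / w, 0.0), 1.0)
                    if rng.random() < p:
                        base = want
                    else:
                        others = [b for b in "ACGT" if b != want]
                        base = others[rng.integers(0, 3)]
                    gbase = base if strand == "+" else base.translate(COMPLEMENT)
                    self._pin(chrom, gpos, gbase)
                self.site_base[key] = base
                tally[r["cluster"]] = (seen + w, hits + w * (base == want))

    # --- read emission ----------------------------------------------------
    def _interval(self, p5: int, length: int, strand: str) -> tuple[int, int]:
        if strand == "+":
            return p5, p5 + length
        return p5 - length + 1, p5 + 1

    def add_read(self, rep, spec, strand, p5, length, rng, role, pair_id=-1):
        start, end = self._interval(p5, length, strand)
        chrom_len = len(self.genome[spec.chrom])
        if start < 4 or end > chrom_len - 4:
            return False
        self.rows.append(
            dict(replicate=rep, cluster=id(spec), chrom=spec.chrom, start=start,
                 end=end, strand=strand, role=role, pair_id=pair_id,
                 methyl3p=bool(rng.random() < spec.methyl3p_frac),
                 _u1=spec.u1_bias, _a10=spec.a10_bias)
        )
        return True

    def next_pair_id(self) -> int:
        self._pair_id += 1
        return self._pair_id

    # --- sequence extraction (after all pins) -----------------------------
    def extract(self, rng_tails: np.random.Generator) -> pd.DataFrame:
        cfg = self.config
        genome = {c: bytes(b).decode() for c, b in self.genome.items()}
        rows = []
        for r in self.rows:
            r.pop("_u1", None)
            r.pop("_a10", None)
        for i, r in enumerate(self.rows):
            core = genome[r["chrom"]][r["start"]:r["end"]]
            if r["strand"] == "-":
                core = core.translate(COMPLEMENT)[::-1]
            tail = ""
            if cfg.tail_prob > 0 and rng_tails.random() < cfg.tail_prob:
                k = int(_sample(rng_tails, cfg.tail_length_dist))
                for j in range(k):
                    if r["strand"] == "+":
                        cont = genome[r["chrom"]][r["end"] + j]
                    else:
                        cont = genome[r["chrom"]][r["start"] - 1 - j].translate(COMPLEMENT)
                    base = str(_sample(rng_tails, cfg.tail_nt_dist))
                    while base == cont:  # force nontemplated at every position
                        base = str(_sample(rng_tails, cfg.tail_nt_dist))
                    tail += base
            rows.append({**r, "read_id": f"sim{i}", "seq": core + tail, "tail": tail})
        frame = pd.DataFrame(rows)
        self.final_genome = genome
        return frame


def plant_reads(
    config: SimConfig, genome: dict[str, str]
) -> tuple[list[pd.DataFrame], TruthAnnotation, dict[str, str]]:
    """Draw per-replicate read sets from the planted cluster specs.

    Returns per-replicate collapsed read frames, the ground-truth
    annotation, and the genome *after* bias pinning (the genome every
    emitted non-tail read matches exactly).
    """
    for spec in config.cluster_specs:
        if spec.chrom not in genome or spec.end > len(genome[spec.chrom]):
            raise ConfigurationError(f"cluster outside genome: {spec.chrom}:{spec.start}-{spec.end}")
    planter = _Planter(config, genome)

    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed % (2**31), 7919, rep])
        for spec in config.cluster_specs:
            n = int(rng.poisson(spec.expression))
            if n <= 0:
                continue
            lengths = list(spec.length_dist)
            lprobs = np.asarray([spec.length_dist[k] for k in lengths], float)
            lprobs /= lprobs.sum()

            n_pp = int(round(spec.pingpong_frac * n / 2)) * 2
            n_oh = int(round(spec.overhang_frac * n / 2)) * 2
            n_rest = max(n - n_pp - n_oh, 0)

            def draw_len():
                return int(lengths[rng.choice(len(lengths), p=lprobs)])

            def main_strand():
                return "+" if rng.random() < spec.strand_bias else "-"

            def get_lattice(strand: str) -> list:
                """Fixed per-cluster fragmentation lattice (discrete 5'
                cleavage sites), shared across replicates; see the phased
                emission below."""
                lattices = planter.lattices.setdefault(id(spec), {})
                if strand not in lattices:
                    sites = []
                    span = spec.end - spec.start
                    n_sites = max(2, span // 600)
                    stride = span / n_sites
                    for si in range(n_sites):
                        # stratified: one jittered start per stride, so
                        # the lattice covers the whole planted span
                        lo = spec.start + int(si * stride)
                        hi = min(lo + int(stride), spec.end - 40)
                        p5 = int(rng.integers(lo, max(hi, lo + 1)))
                        if strand == "-":
                            p5 = min(p5 + 40, spec.end - 1)
                        frags = []
                        while len(frags) < 12:
                            L = draw_len()
                            s, e = planter._interval(p5, L, strand)
                            if s < spec.start or e > spec.end:
                                break
                            frags.append((p5, L))
                            p5 = p5 + L if strand == "+" else p5 - L
                        if frags:
                            sites.append(frags)
                    lattices[strand] = sites
                return lattices[strand]

            # slicer (ping-pong) partner pairs: secondary 5' end sits
            # opposite position 10 of the primary, so the 5' overlap is
            # 10 nt.  In phased clusters the primary is itself a phased
            # product, so its 5' end is drawn from the lattice.
            for _ in range(n_pp // 2):
                L1, L2 = draw_len(), draw_len()
                strand = main_strand()
                pid = planter.next_pair_id()
                for _try in range(50):
                    lattice = get_lattice(strand) if spec.phased else None
                    if lattice:
                        site = lattice[rng.integers(0, len(lattice))]
                        p5, L1 = site[rng.integers(0, len(site))]
                    elif strand == "+":
                        p5 = int(rng.integers(spec.start, spec.end - L1))
                    else:
                        p5 = int(rng.integers(spec.start + L1, spec.end))
                    q5 = p5 + 9 if strand == "+" else p5 - 9
                    other = "-" if strand == "+" else "+"
                    s1, e1 = planter._interval(p5, L1, strand)
                    s2, e2 = planter._interval(q5, L2, other)
                    if min(s1, s2) >= spec.start and max(e1, e2) <= spec.end:
                        break
                ok = planter.add_read(rep, spec, strand, p5, L1, rng,
                                      "pingpong_primary", pid)
                if ok and not planter.add_read(rep, spec, other, q5, L2, rng,
                                               "pingpong_secondary", pid):
                    planter.rows.pop()  # keep pair ids symmetric

            # Dicer duplex pairs: plus [s, s+L) with minus [s-2, s+L-2),
            # i.e. a 2-nt 3' overhang on both duplex ends
            for _ in range(n_oh // 2):
                L = draw_len()
                pid = planter.next_pair_id()
                s = int(rng.integers(spec.start + 2, spec.end - L))
                ok = planter.add_read(rep, spec, "+", s, L, rng, "duplex_plus", pid)
                if ok and not planter.add_read(rep, spec, "-", s + L - 3, L, rng,
                                               "duplex_minus", pid):
                    planter.rows.pop()

            # remaining reads: phased head-to-tail tiling or unstructured.
            # Phased precursors reuse a fixed per-cluster fragmentation
            # lattice (discrete 5' cleavage sites), as head-to-tail
            # processing from recurrent precursor start sites produces;
            # chains emit the lattice from its 5' end for a random number
            # of fragments, so 5'-to-5' spacings follow the length
            # distribution.
            emitted = 0
            if spec.phased:
                while emitted < n_rest:
                    strand = main_strand()
                    sites = get_lattice(strand) or get_lattice("+" if strand == "-" else "-")
                    site = sites[rng.integers(0, len(sites))]
                    n_frag = int(rng.integers(3, 10))
                    for p5, L in site[:n_frag]:
                        if emitted >= n_rest:
                            break
                        if planter.add_read(rep, spec, strand, p5, L, rng, "phased"):
                            emitted += 1
            else:
                for _ in range(n_rest):
                    L = draw_len()
                    strand = main_strand()
                    if strand == "+":
                        p5 = int(rng.integers(spec.start, spec.end - L))
                    else:
                        p5 = int(rng.integers(spec.start + L, spec.end - 1))
                    planter.add_read(rep, spec, strand, p5, L, rng, "single")

    rng_pins = np.random.default_rng([config.seed % (2**31), 15485863])
    planter.apply_pins(rng_pins)
    rng_tails = np.random.default_rng([config.seed % (2**31), 104729])
    all_reads = planter.extract(rng_tails)

    cluster_names = {id(s): f"truth_{i}_{s.klass}" for i, s in enumerate(config.cluster_specs)}
    if not all_reads.empty:
        all_reads["cluster"] = all_reads["cluster"].map(cluster_names)
    truth_clusters = pd.DataFrame(
        [
            dict(chrom=s.chrom, start=s.start, end=s.end,
                 name=s.klass, score=s.expression, strand="+",
                 cluster=cluster_names[id(s)], strand_bias=s.strand_bias)
            for s in config.cluster_specs
        ]
    )
    truth = TruthAnnotation(clusters=truth_clusters, reads=all_reads)

    reads_by_rep = []
    for rep in range(config.n_replicates):
        sub = all_reads[all_reads["replicate"] == rep] if not all_reads.empty else all_reads
        if sub.empty:
            reads_by_rep.append(pd.DataFrame(columns=oio.READ_COLUMNS))
            continue
        collapsed = (
            sub.groupby(["seq", "methyl3p"], as_index=False)
            .agg(count=("seq", "size"), read_id=("read_id", "first"))
        )
        reads_by_rep.append(collapsed[oio.READ_COLUMNS].reset_index(drop=True))
    return reads_by_rep, truth, planter.final_genome


def emit_fixtures(
    reads_by_replicate: list[pd.DataFrame],
    truth: TruthAnnotation,
    config: SimConfig,
    outdir: str | Path,
    genome: dict[str, str] | None = None,
    fmt: str = "fasta",
) -> dict[str, Path]:
    """Write per-replicate read files, the truth BED and the spike-in TSV.

    Spike-in reads are appended to every replicate at ``config.spikein_copies``
    copies each.  ``fmt`` selects collapsed FASTA or expanded FASTQ.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    spike_rows = pd.DataFrame(
        [
            dict(read_id=name, seq=oio.normalize_seq(seq),
                 count=config.spikein_copies, methyl3p=methyl)
            for name, seq, methyl in config.spikeins
        ]
    )
    for rep, reads in enumerate(reads_by_replicate):
        combined = pd.concat([reads, spike_rows], ignore_index=True) if len(spike_rows) else reads
        name = f"reads_rep{rep}.{'fa' if fmt == 'fasta' else 'fastq'}"
        writer = oio.write_collapsed_fasta if fmt == "fasta" else oio.write_fastq
        paths[f"reads_rep{rep}"] = writer(combined, outdir / name)
    paths["truth_bed"] = oio.write_bed(truth.clusters, outdir / "truth_clusters.bed")
    paths["spikeins"] = oio.write_spikein_tsv(config.spikeins, outdir / "spikeins.tsv")
    if genome is not None:
        paths["genome"] = oio.write_genome_fasta(genome, outdir / "genome.fa")
    return paths


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate genome + reads + truth in one call (optionally writing files)."""
    genome = generate_genome(config)
    reads_by_rep, truth, genome = plant_reads(config, genome)
    if outdir is not None:
        emit_fixtures(reads_by_rep, truth, config, outdir, genome=genome)
    return SimResult(config=config, genome=genome,
                     reads_by_replicate=reads_by_rep, truth=truth)


def default_study_config(seed: int = 0, clusters_per_class: int = 10,
                         expression: float = 600.0) -> SimConfig:
    """The default study layout: three chromosomes, ``clusters_per_class``
    planted clusters per class spaced >= 12 kb apart, six replicates and
    sparse background reads on a cluster-free chromosome."""
    n_per_chrom = clusters_per_class  # one class per chromosome
    spacing = 12_000
    chrom_len = max(20_000, (n_per_chrom + 1) * spacing + 10_000)
    specs = []
    for ci, klass in enumerate(("piRNA", "endo-siRNA", "os-piRNA")):
        chrom = f"chr{ci + 1}"
        for j in range(n_per_chrom):
            start = 6_000 + j * spacing
            specs.append(
                PlantedClusterSpec(chrom=chrom, start=start, end=start + 3_000,
                                   klass=klass, expression=expression)
            )
    # background-only chromosome: sparse unstructured reads, no cluster truth
    specs.append(
        PlantedClusterSpec(chrom="chr4", start=1_000, end=chrom_len - 1_000,
                           klass="background", expression=60.0)
    )
    return SimConfig(
        genome_length=[chrom_len] * 4,
        cluster_specs=specs,
        n_replicates=6,
        seed=seed,
        tail_prob=0.0,
    )


def config_from_dict(payload: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (YAML-friendly)."""
    payload = dict(payload)
    specs = [
        PlantedClusterSpec(**{**s, "length_dist": {int(k): v for k, v in s["length_dist"].items()}
                              if s.get("length_dist") else None})
        for s in payload.pop("cluster_specs", [])
    ]
    if "tail_length_dist" in payload:
        payload["tail_length_dist"] = {int(k): v for k, v in payload["tail_length_dist"].items()}
    if "spikeins" in payload:
        payload["spikeins"] = [tuple(s) for s in payload["spikeins"]]
    return SimConfig(cluster_specs=specs, **payload)


def config_to_dict(config: SimConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["spikeins"] = [list(s) for s in config.spikeins]
    return payload
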