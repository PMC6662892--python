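"""End-to-end pipeline: simulate -> map -> annotate -> clusters -> signatures
-> tails/oxidation, with a checksummed run manifest for reproducibility.

All thresholds default to the study values: 5-kb windows / 1-kb steps,
>= 5 sequences (>= 1 unique), density floor 10/kb, length > 100 bp, the
0.75 class fractions, the 0.10 overhang and 0.01 ping-pong ratios,
RPM >= 20 in >= 4 replicates, isomiR offsets +/-2, 1-4-nt tails, <= 2
consensus mismatches, methylation coverage >= 5 / ratio >= 0.25 / >= 10
cytosines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ospi import annotation, clusters as cl, signatures as sig, tailing
from ospi import simulate as sim
from ospi.mapping import GenomeIndex, map_reads, reallocate_multimappers

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    outdir: str = "ospi_run"
    seed: int = 0
    # inputs: either a simulation config or paths to real files
    simulate: bool = True
    sim_config: dict | None = None
    genome_fasta: str | None = None
    reads: list[str] = field(default_factory=list)
    spikein_tsv: str | None = None
    # thresholds (study defaults)
    window: int = 5000
    step: int = 1000
    min_seqs: int = 5
    min_unique: int = 1
    density_floor: float = 10.0
    min_len: int = 100
    min_rpm: float = 20.0
    min_reps: int = 4
    max_trim: int = 4
    survival_unmethylated: float = 0.0
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "map", "annotate", "clusters", "signatures", "tails",
    ])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path

    def validate(self) -> None:
        if not self.simulate:
            if self.genome_fasta is None:
                raise ValueError("config error: genome_fasta required when simulation is disabled")
            if not self.reads:
                raise ValueError("config error: reads required when simulation is disabled")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in fixed order; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "files": {}}
    state: dict = {}

    def record(name: str, path: Path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        logger.info("stage %s", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        manifest["stages"].append(name)

    def stage_simulate():
        if config.simulate:
            sim_cfg = (sim.config_from_dict(config.sim_config)
                       if config.sim_config else sim.default_study_config(seed=config.seed))
            result = sim.simulate(sim_cfg, outdir=outdir / "sim")
            state["genome"] = result.genome
            state["reads"] = result.reads_by_replicate
            state["spikeins"] = pd.DataFrame(sim_cfg.spikeins, columns=["name", "seq", "methyl3p"])
            for p in sorted((outdir / "sim").iterdir()):
                record(f"sim/{p.name}", p)
        else:
            from ospi import io as oio
            state["genome"] = oio.read_genome_fasta(config.genome_fasta)
            state["reads"] = [oio.read_reads(p) for p in config.reads]
            state["spikeins"] = (oio.read_spikein_tsv(config.spikein_tsv)
                                 if config.spikein_tsv else None)

    def stage_map():
        index = GenomeIndex(state["genome"])
        state["index"] = index
        aln_by_rep, unmapped_by_rep, totals = [], [], []
        for reads in state["reads"]:
            reads, _removed = annotation.filter_low_complexity(reads)
            if state.get("spikeins") is not None:
                spike_counts, reads = annotation.match_spikeins(reads, state["spikeins"])
                state.setdefault("spike_counts", []).append(spike_counts)
            aln, unmapped = map_reads(reads, index)
            aln = reallocate_multimappers(aln)
            aln_by_rep.append(aln)
            unmapped_by_rep.append(unmapped)
            totals.append(float(aln["wcount"].sum()))
        state["aln_by_rep"] = aln_by_rep
        state["unmapped_by_rep"] = unmapped_by_rep
        state["totals"] = totals
        summary = pd.DataFrame({"replicate": range(len(totals)), "genome_mapped": totals})
        path = outdir / "mapping_summary.tsv"
        summary.to_csv(path, sep="\t", index=False)
        record("mapping_summary", path)

    def stage_annotate():
        # no known-RNA tracks in a pure simulation run; category summary only
        frames = []
        for rep, aln in enumerate(state["aln_by_rep"]):
            assignments = annotation.assign_known(aln, tracks={})
            summary = annotation.category_summary(aln, assignments)
            summary.insert(0, "replicate", rep)
            frames.append(summary)
        path = outdir / "annotation_summary.tsv"
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        record("annotation_summary", path)

    def stage_clusters():
        result = cl.predict_all_classes(
            state["aln_by_rep"], state["totals"],
            min_rpm=config.min_rpm, min_reps=config.min_reps,
            window=config.window, step=config.step, min_seqs=config.min_seqs,
            min_unique=config.min_unique, density_floor=config.density_floor,
            min_len=config.min_len,
        )
        state["clusters"] = result
        rows = []
        for klass, cs in result.items():
            for c in cs:
                rows.append(dict(
                    chrom=c.chrom, start=c.start, end=c.end, name=klass,
                    score=round(c.weighted_count, 2), strand=c.main_strand,
                    frac_length=round(c.frac_length_in_range, 4),
                    frac_1U_or_10A=round(c.frac_1U_or_10A, 4),
                    frac_main_strand=round(c.frac_main_strand, 4),
                    n_sequences=c.n_distinct_sequences,
                ))
        path = outdir / "clusters.bed"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=True)
        record("clusters", path)

    def stage_signatures():
        pooled = pd.concat(state["aln_by_rep"], ignore_index=True)
        labels = cl.annotate_by_clusters(pooled, state["clusters"])
        state["read_classes"] = labels
        rows = []
        for klass in ("piRNA", "endo-siRNA", "os-piRNA"):
            seqs = set(labels.loc[labels["klass"] == klass, "seq"])
            sub = pooled[pooled["seq"].isin(seqs)]
            if sub.empty:
                continue
            overlap_hist, z10 = sig.pingpong_profile(sub)
            overhang_hist, dicer_frac = sig.overhang_profile(sub)
            phasing_hist = sig.phasing_profile(sub)
            _, f1u, f10a, fboth = sig.composition_profile(sub)
            rows.append(dict(
                klass=klass,
                modal_overlap=sig.modal_distance(overlap_hist),
                zscore_overlap10=round(z10, 3),
                modal_phasing=sig.modal_distance(phasing_hist),
                dicer_overhang_fraction=round(dicer_frac, 4),
                frac_1U=round(f1u, 4), frac_10A=round(f10a, 4),
                frac_1U_and_10A=round(fboth, 4),
                strand_fraction=round(sig.strand_bias(sub), 4),
            ))
        path = outdir / "signatures.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        record("signatures", path)

    def stage_tails():
        pooled_unmapped = pd.concat(state["unmapped_by_rep"], ignore_index=True)
        cluster_sets = {k: v for k, v in state["clusters"].items()
                        if k in ("piRNA", "os-piRNA")}
        pooled = pd.concat(state["aln_by_rep"], ignore_index=True)
        labels = state.get("read_classes")
        perfect = None
        if labels is not None:
            merged = pooled.merge(labels, on="seq", how="left")
            perfect = {k: float(merged.loc[merged["klass"] == k, "wcount"].sum())
                       for k in cluster_sets}
        tails, ratios = tailing.detect_tails(
            pooled_unmapped, state["index"], cluster_sets,
            perfect_counts=perfect, max_trim=config.max_trim,
        )
        path = outdir / "tails.tsv"
        tails.to_csv(path, sep="\t", index=False)
        record("tails", path)
        if ratios is not None:
            path = outdir / "tailing_ratios.json"
            path.write_text(json.dumps(ratios, indent=2))
            record("tailing_ratios", path)

    run_stage("simulate", stage_simulate)
    run_stage("map", stage_map)
    run_stage("annotate", stage_annotate)
    run_stage("clusters", stage_clusters)
    run_stage("signatures", stage_signatures)
    run_stage("tails", stage_tails)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
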