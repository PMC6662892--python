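# Methods

This note documents the models, conventions and numerical choices behind
`ospi`, the assumptions of the synthetic-data generator, and what the
package's validation does and does not show about real data.

## Coordinates and alphabets

All intervals are 0-based half-open (BED convention). The 5′ end of a
plus-strand alignment `[s, e)` is `s`; of a minus-strand alignment, `e − 1`.
Reads are stored in the DNA alphabet (U → T); "1U" therefore tests for a
5′ T in file space. Weighted ("read count") statistics use
`count × weight` after multimapper reallocation; "sequence" statistics
count distinct sequence strings once, unweighted. This read-count /
sequence-count split is applied consistently across all cluster criteria.

## Mapping and reallocation

Mapping is exact (zero mismatches) over both strands, via a 17-mer prefix
index with full-length verification; 17 nt is the minimum accepted read
length, so every read has a seed. Reads outside 17–40 nt are dropped;
reads with ≥75 % of one nucleotide are removed as low-complexity (boundary
inclusive). Multimapped sequences are apportioned across their loci by
local unique-read density: locus *i* receives weight *U*ᵢ/Σ*U*ⱼ, where *U*ᵢ
sums the counts of uniquely mapped reads whose 5′ ends fall within ±5 kb of
locus *i*'s 5′ end, pooling both strands. If no unique read falls near any
locus the count is split equally. The flank width, and the choice to pool
strands, are exposed as parameters; strand-specific weighting is a
plausible alternative the package does not default to.

## Cluster discovery and classification

The scan slides 5-kb windows in 1-kb steps; a window seeds a candidate when
it holds ≥5 distinct sequences of the candidate type with ≥1 uniquely
mapped (a stricter ≥2-unique mode is exposed via `min_unique`). Overlapping
qualifying windows are unioned before trimming — deterministic and
order-independent. Boundaries are then trimmed inward in 1-kb edge bins
while the edge bin's density is below 10 distinct sequences per kb, with
one guard: the density rule determines *boundaries*, not existence, so the
last read-bearing bin is never removed — a seeded window always yields a
candidate, clipped to its read extent. Without this guard any cluster
whose ≥5 sequences sit inside a single kilobase would be erased by its own
boundary rule. Final candidates must exceed 100 bp (strict).

Class criteria follow the quoted-threshold wording literally: every
"more than X %" is strict (a cluster at exactly 75 % main-strand fails);
every "at least N" / "≥" is inclusive (RPM exactly 20 passes; exactly 4
duplex sequences pass). Membership of a read in a window, bin or cluster
is by its 5′-end coordinate, which makes window counts, trimming and
per-cluster statistics mutually consistent.

Duplex detection requires both 3′-overhang offsets of an opposite-strand
pair to equal 2 (`plus.end − minus.end` and `plus.start − minus.start`);
ping-pong detection requires a 5′-overlap of exactly 10 with both reads
covering the overlapped span. Prediction is sequential — piRNA from
25–40-nt reads, endo-siRNA from 17–24-nt reads, os-piRNA from the 17–24-nt
reads left after removing those in accepted endo-siRNA clusters — so no
sequence is counted in two classes. Clusters are called per replicate;
accepted intervals are unioned per class and the union intervals kept at
RPM ≥ 20 in ≥4 replicates (per-replicate RPM uses that replicate's total
genome-mapped weighted count).

## Signature statistics

* **5′ overlap** between plus `[ps,pe)` and minus `[ms,me)`:
  `d = me − ps`, valid when `d > 0`, `ms ≤ ps` and `me ≤ pe` (both reads
  cover the overlapped 5′-proximal span):

  ```
  plus   ps ────────────→ pe
  minus    ms ←──────── me
           |← d = me−ps →|   (5′ ends: ps and me−1)
  ```

  The ping-pong histogram adds min(pair weighted counts) at each `d`,
  mirroring the phasing min-count rule (the pairing score is a documented
  knob; product and pair-count alternatives would shift scale, not mode).
  The z-score contrasts hist[10] with the mean/sd of hist[1..9, 11..20].
* **3′ overhang**: both offsets of every overlapping opposite-strand pair
  are recorded; the Dicer fraction is (sequences in ≥1 exact-2/2 duplex) /
  (sequences in ≥1 complementary pair).
* **Phasing**: counts are aggregated per distinct (chrom, strand, 5′
  position) with multimapper counts divided by their number of loci (not
  the density weights — the two weightings serve different analyses);
  adjacent distinct positions are paired in transcript orientation and each
  pair scores min(count up, count down). An all-pairs mode within a
  configurable distance is available; adjacent pairing is the default.

## The synthetic-data generator

The generator emulates the read-level structure the analyses detect, per
planted cluster: class length distributions (modes 30 / 22 / 20 nt for
piRNA / endo-siRNA / os-piRNA), 1U and 10A biases, strand bias, slicer
pairs (5′ overlap exactly 10), Dicer duplexes (both overhangs exactly 2),
head-to-tail phasing, nontemplated 1–4-nt 3′ tails, per-read 3′-methyl
flags, and six spike-ins of which three are 3′-2′-O-methylated (the
spike-in sequences themselves are synthetic stand-ins; only the design
counts matter to the analyses). Read counts per cluster and replicate are
Poisson around the configured expression — no overdispersion model is
claimed. Defaults: 6 replicates, 3-kb clusters at expression 600 per
replicate, strand bias 0.9 (the criteria only bound it below at 0.75),
u1 bias 0.85, ping-pong fraction 0.25 for os-piRNA, duplex fraction 0.6
for endo-siRNA, methylation 0.95 for piRNA and 0 for os-piRNA/endo-siRNA.

Two generator mechanisms deserve explanation:

* **Base pinning.** Reads must match the genome at their loci, so 1U/10A
  biases are realised by pinning template bases before read extraction.
  All 5′-base pins are applied before any position-10 pin (the 5′ identity
  is the stronger class signature and wins contested bases). Decisions are
  made once per 5′ site, weighted by the site's read multiplicity, with a
  clamped greedy controller that keeps each cluster's realised read-level
  fraction at its configured bias even when a few sites carry most reads;
  sites whose base is already forced simply record the forced outcome. In
  ping-pong pairs one pinned base serves double duty — the primary's
  position-10 A is the complement of the secondary's 5′ U — reproducing the
  biological coupling.
* **Phasing lattices.** Phased clusters own a fixed per-strand
  fragmentation lattice: stratified precursor start sites (one per ~600 bp,
  covering the span) each carrying one drawn fragment chain. Emission
  replays a lattice chain from its 5′ end for a random number of fragments.
  Discrete, reused cleavage sites are what give real phased data a
  5′-to-5′ mode at the read length; fully random chain starts would smear
  the mode into adjacent-distance-1 noise. In phased clusters, ping-pong
  primaries are drawn from the lattice as well.

What the simulation does **not** model: sequencing error, adapters and
quality variation (constant Q40), expression overdispersion, repeat-driven
multimapping structure of real genomes, partial (wobble) ping-pong
overlaps, and genome-scale cluster-density contrasts. Passing recovery
tests therefore demonstrates the correctness of the operations under their
own assumptions — geometry, thresholds, weighting, determinism — not
performance on real libraries.

## Tailing and oxidation

A read failing perfect mapping is tail-called when trimming k = 1..4 bases
(smallest k wins) leaves a ≥17-nt core mapping perfectly inside a retained
os-piRNA/piRNA cluster, with the trimmed bases differing from the genomic
continuation at ≥1 position — the operational meaning of "nontemplated".
The class tailing ratio is tailed / (perfect + tailed) weighted counts; a
tailed core hitting several retained clusters splits its count equally
across the hits. In-silico oxidation keeps 3′-2′-O-methylated reads and
removes the rest (deterministically at the default survival of 0;
binomial count thinning otherwise), so an os-piRNA population with
methylation fraction 0 vanishes while piRNAs persist.

## Feature annotation and statistics

Gene elements are assigned in the fixed order CDS, 5′UTR, 3′UTR,
coding-gene intron, noncoding-gene exon, noncoding-gene intron — first
overlapping class wins; within a class a sense overlap beats antisense;
remainder intergenic. TEs likewise: LINE, LTR, SINE, DNA, other-repeat
bodies, then the ten 0–1-kb (FL1k) and 1–2-kb (FL2k) flank classes,
remainder non-repeat; a read spanning a body edge is body. The shuffle
background re-places each read uniformly on its own chromosome preserving
length, 100 times by default; enrichment is observed / mean-background.

Differential TE targeting ranks TEs by abundance (descending) within each
replicate of each class and compares per-TE rank vectors with Welch's
t-test (Student optional); when both groups have zero rank variance,
unequal means are reported as p = 0 (flagged significant) and equal means
as t = 0, p = 1. Bonferroni multiplies by the number of TEs tested after
removing rRNA/tRNA/srpRNA/unknown-derived entries.

Region methylation: cytosines with coverage ≥5 are detected; sites with
methylated/coverage ≥ 0.25 count as methylated; a region reports the
methylated/detected ratio per context group (CpG vs pooled CHG+CHH) and NA
below 10 detected cytosines. Duplicate call rows are dropped, making the
computation order-invariant.

## Problem sizes and determinism

Validation runs use toy genomes of 40–570 kb, clusters of 3 kb, and
10³–10⁴ reads per replicate — sizes at which every pairing operation can be
cross-checked against exhaustive all-pairs oracles and every locus set
against a naive all-offsets scan. All randomness flows from
`numpy.random.default_rng` seeded from a single configuration seed;
identical configurations produce byte-identical outputs, which the
pipeline's checksummed manifest makes verifiable end to end.

## Known limitations

Exact-match mapping cannot place reads over SNVs or sequencing errors
(externally aligned BED can be imported instead). isomiR detection covers
templated 3′ variants only. The ping-pong z-score uses a simple
neighbouring-bin background rather than permutation nulls. The
cluster-boundary resolution is 1 kb plus read-extent clipping.
LiftOver-based cross-species comparisons, secondary-structure prediction
and precursor transcription quantification are out of scope.
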