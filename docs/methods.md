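# Methods

## The finishing model

`rdnafinish` treats genome finishing as a planning problem over a draft
assembly. The central biological fact is that bacterial rDNA operons —
16S (~1.5 kb), intragenic spacer (ITS, ~0.4–0.6 kb), 23S (~2.9 kb) and 5S
(~0.12 kb) — occur in multiple near-identical copies, each longer than a
short-read insert, so assemblies break at them systematically. Three
signatures follow, and the toolkit detects all three: whole operons inside
inter-contig gaps, gene fragments at contig termini, and short chimeric
rRNA-only contigs.

Wet-lab steps are replaced by in-silico analogs. PCR is simulated by
hybridization-site search plus convergent-site pairing; Sanger reads are
modeled as a fixed readable span downstream of a sequencing primer's 3′
end — 750 bp for coverage guarantees, 1000 bp reported as the best case.

## The parallel walk plan

For a gap amplicon shown (by the universal pairs) to contain a complete
operon, six reactions are planned: the two gap primers read inward from
the amplicon ends, U1 (a 16S reverse primer sited near the 16S 5′ end)
reads back across the left flank, U2 (16S forward, near the 16S 3′ end)
and U3 (23S reverse, near the 23S 5′ end) tile the spacer bidirectionally,
and U4 (23S forward, near the 23S 3′ end) reads across the 5S into the
right flank. No reaction depends on another's outcome, so the stage
equivalent is ceil(6/2) = 3 compared to `ceil(gap / 1500)` serial stages of
traditional bidirectional walking (five stages for the average 7.5 kb
gap).

Coverage accounting treats the 16S/23S/5S gene *interiors* as known — the
consensus genes exist by construction, which is precisely why the strategy
works — so "uncovered" means unknown template (flanks, spacer) reached by
no predicted read. A planted complete-operon amplicon with ≤ 1.5 kb spacer
has an empty uncovered set; a pathological 2.5 kb spacer correctly reports
an uncovered interval that the two 750 bp spacer reads cannot tile. When a
universal primer lacks a usable site (a mutated footprint), its segment
degrades to traditional walking and the plan records which segment.

## Key parameters

| parameter | default | why |
|---|---|---|
| rDNA scan identity / min fragment | 90 % / 100 bp | tolerates inter-copy divergence (copies are similar, not identical) while excluding chance matches |
| mask rule | length < 2000 bp AND rDNA fraction ≥ 0.8 | "short contigs comprised essentially of rRNA"; 0.8 absorbs alignment edge effects |
| contig-end window | 200 bp | a fragment is "at" a terminus within this window |
| operon clustering span | 10 kb | an operon's genes fit well inside; separate copies are far apart |
| N-stretch minimum | 3 bp | the smallest run an assembler emits deliberately |
| placement flank window / identity | 300 bp / 0.95 | a small contig must reproduce both host flanks nearly exactly |
| placement length tolerance | ±50 % of stretch length | N-run lengths are estimates, not measurements |
| gap primer offsets | 250–350 bp inside each contig end | leaves the terminal (often rDNA-fragment-bearing) sequence inside the amplicon while keeping primers in unique sequence |
| universal product windows | 16S 1200–1700 bp, 23S 1800–2400 bp | bracket the canonical gene lengths amplified by 8F/1492R and 127F/2241R |
| primer constraints | 18–25 nt, Tm 55–65 °C, GC 40–60 %, unique site in the draft | standard Sanger/PCR oligo practice |
| Tm model | nearest-neighbor (unified parameters), 50 mM Na⁺, 500 nM oligo; degenerate bases by minimum-Tm expansion | conservative annealing estimate |
| hybridization stringency | ≤ 2 mismatches, exact 3′-terminal 3 nt | 3′ mismatches block extension; template N never matches (unknown base ≠ evidence) |
| anchor k-mer | 21 | unique in a ~6 Mb genome with overwhelming probability; repeats (rDNA above all) anchor poorly *by design* |
| rearrangement windows | 10 kb / 5 kb step | breakpoints localized to ± one step |
| min placement jump | 50 kb | separates true rearrangements from local jitter |
| validation thresholds | identity ≥ 99 %, coverage ≥ 0.99 of non-N bases | a finished sequence should contain the draft essentially verbatim |

## The synthetic data generator

The generator emulates a ~6 Mb, 45 % GC *Paenibacillus*-like chromosome
with 12 operon copies diverging 2 % from a single master operon, with
per-copy spacer-length jitter (400–600 bp). Universal-primer footprints
are planted at their canonical positions (8F at the 16S start, 1492R at
its end; 127F ending at 23S position 127, 2241R at position 2241) and kept
mutation-free, so universal primers always find their sites — the operons
are synthesized de novo around these fixed footprints rather than copied
from any real rRNA, keeping the repository free of external sequence data.
At zero divergence the copies are literally identical (no jitter).

Draft corruption applies the documented failure modes in order: one
segmental relocation (200 kb by default, destination interior to a future
contig, with an N-stretch planted just before the junction); cuts at 12
operons such that the left contig keeps 200 bp of 16S and the right contig
keeps the 5S region (ends carry detectable fragments while gap primers
still sit in unique sequence); five rDNA-free gaps sized 10–14 kb so the
mean gap is near 7.5 kb; 198 N-runs of 9–769 bp, ten of which replace
excised unique segments re-emitted as placeable small contigs (N length
jittered ±20 % of the true excision, exercising the placement tolerance);
ten rRNA-isoform contigs sliced from operon copies at 0.3 % extra
divergence (each < 2 kb and ≥ 80 % rDNA, so masking recall is 100 % by
construction and precision is the tested quantity); random orientation
flips; and renaming by descending length. The recorded truth inverts every
operator; `reconstruct_genome` must return the source genome
byte-identically, and the test suite asserts this across twenty seeds.

A linear genome is emulated, so 18 main contigs give 17 inter-contig gaps
(a circular chromosome would give 18). The strain-CR1 "4–13"
junction-verification primer pair is planted in an operon-free locus with
a 900 bp product, standing in for the real genome's sub-1-kb junction
product when no accession download is possible.

What the generator does **not** emulate: read-level error models and
coverage fluctuations (no FASTQ simulation), mixed-strand operon copies in
the bundled preset, chimeric junctions *within* rRNA-only contigs,
tandem-repeated non-rDNA elements, and base-composition structure beyond
i.i.d. background at a fixed GC. Passing tests therefore demonstrate that
the planning logic is correct under the documented failure modes, not that
any particular real genome would be finished without manual judgment.

## Numerical and algorithmic choices

- **Scanning** is seed-and-extend: exact 13-mers unique within the gene
  seed diagonal clusters, which are then aligned by edit distance (edlib,
  infix mode, IUPAC equalities on the consensus side). Because infix mode
  must consume the whole query, alignments are clipped to their
  maximum-scoring subsegment (match +1, edit −3; edit-optimal alignment of
  unrelated sequence still matches ~2/3 of columns via free indels, hence
  the asymmetric penalty) before identity is computed.
- **Consensus building** maps each copy onto the longest copy by edit
  alignment; per-column majority wins, ties emit the covering IUPAC code,
  majority-gap columns drop.
- **Site search** is vectorized bitmask comparison (A/C/G/T bits, IUPAC
  codes as unions; template N carries a disjoint bit so it can never
  satisfy a primer).
- **Anchoring** uses k-mers unique in both the reference and the contig
  set (canonical, both strands), extended to maximal exact matches;
  anchors shorter than 2k are discarded. Contig order and gap sizes are
  projected from the anchor nearest each contig end — a deliberately local
  estimate, so an internal misassembled block cannot shift where a
  contig's first bases sit on the reference.
- **Rearrangement calling** segments window placements into collinear runs
  (consistent strand and diagonal offset), keeps the extent-weighted
  monotone backbone, and calls the excluded runs: inversion when the
  strand is flipped, relocation otherwise, re-labeled insertion-at-N when
  a breakpoint abuts an N-stretch. Block boundaries are derived from the
  run's reference extent via its median diagonal, which is tight to about
  one window step (overlapping window extents would inflate it).
- **Validation** verifies contigs in 15 kb chunks, each aligned in the
  window suggested by its own unique-k-mer anchors, with banded edit
  distance escalated only for small pieces; failed pieces bisect down to
  500 bp, and pieces whose true home lies elsewhere (a misassembled block)
  re-anchor themselves. N bases are excluded from identity and coverage
  denominators; the final sequence is doubled so origin-spanning contigs
  of a circular genome place contiguously.
- **Determinism**: every stochastic step draws from one
  `numpy.random.default_rng(seed)`; ties in primer design break by
  Tm-closeness, then GC-closeness, then leftmost position; re-running any
  stage on identical inputs is bit-identical.

## Problem sizes

The bundled study-condition preset runs the full 6 Mb / 38-contig workflow
end to end in a few minutes on one CPU; the property suites use 0.8–1.2 Mb
genomes with proportionally scaled corruption profiles, and oracle
equivalences (N50, primer-site search) run on a thousand random instances
each.

## Known limitations

- A transposition whose travel distance is smaller than the displaced
  intervening segment is geometrically ambiguous ("block moved right" vs
  "segment moved left"); the caller reports the smaller-extent
  interpretation. The recovery guarantee applies in the identifiable
  regime, where the block travels further than its own size.
- Operon copies nested within 10 kb of each other on the same strand would
  merge into one operon call.
- Primer design screens neither hairpins nor primer-dimers, and in-silico
  PCR ranks off-targets by mismatch count only, with no thermodynamic
  model of mispriming.
- Gap classification requires an amplicon; without a PCR-template genome
  the gap stays "unknown" and receives a traditional plan.
- The masking step sets rRNA-only contigs aside (they re-enter only at
  validation); it does not attempt to assign each isoform contig to a
  specific operon copy.
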