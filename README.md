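# rdnafinish

An rDNA-operon-aware planning toolkit for finishing draft bacterial
genomes.

## The problem

Short-read shotgun assembly of a bacterial genome yields a *draft*: dozens
of contigs with no mutual order, riddled with ambiguous-base (N) stretches
and occasional large misassemblies. The dominant culprit is the ribosomal
RNA (rDNA) operon — the 16S–ITS–23S(–5S) gene cluster present in many
near-identical copies per genome, each longer than any short-read insert.
Operons end up inside inter-contig gaps, rRNA gene fragments pile up at
contig boundaries, and short chimeric rRNA-only contigs assemble from reads
belonging to several loci at once.

`rdnafinish` turns that liability into leverage. Because the 16S and 23S
genes are conserved, universal primer pairs (8F/1492R for 16S, 127F/2241R
for 23S) reveal — from a gap amplicon alone — whether an operon sits in a
gap, and four operon-walking primers (U1–U4, hybridizing near the 5′ and 3′
ends of both genes) let *all* the unknown sequence around a complete operon
be Sanger-sequenced in **six parallel reactions**: the work equivalent of
three serial stages of blind primer walking, with no waiting between
stages. The package implements the full finishing workflow around this
idea, with wet-lab PCR and Sanger steps replaced by in-silico PCR and a
750–1000 bp read-span model.

The stages, in order:

1. **QC statistics** — N50 (the contig size at which, together with all
   longer contigs, half the assembly's bases are accounted for), Q30
   fraction (share of bases with Phred quality `Q = −10·log₁₀ e ≥ 30`),
   and fold coverage.
2. **rRNA contig masking** — scan contigs with 16S/23S/5S consensus genes;
   set aside short (< 2 kb) contigs comprised essentially of rRNA.
3. **Contig-end annotation** — flag termini carrying rDNA fragments.
4. **N-stretch handling** — locate every N-run, design a flanking primer
   pair reading across each, and merge small contigs whose ends reproduce
   the host flanks of a stretch.
5. **Reference-guided scaffolding** — order and orient contigs against a
   finished relative via unique-21-mer anchors and estimate gap sizes.
6. **Gap closure planning** — design gap-spanning primers 250–350 bp
   inside each contig end, classify each gap amplicon by rDNA content, and
   emit either the parallel six-reaction plan or a serial
   traditional-walking plan.
7. **Rearrangement screening** — place 10 kb draft windows on the
   reference and call relocations/inversions from discordant runs, with
   junction-verification primers.
8. **Validation** — confirm every original draft contig (masked ones
   included) is represented in the finished sequence.

## Worked example

A synthetic gap amplicon holding one complete operon with 300 bp flanks
(`python examples/parallel_walk_plan.py`):

```
amplicon 5822 bp | 16S product 1550 bp | 23S product 2129 bp | 5S present: True
strategy rdna-parallel: 6 reactions, work of 3 serial walking stages, uncovered: none
  R1_gapF  gapF   + reads [   20,  770)
  R2_U1    U1     - reads [    0,  360)
  R3_U2    U2     + reads [ 1740, 2490)
  R4_U3    U3     - reads [ 1846, 2596)
  R5_U4    U4     + reads [ 5286, 5822)
  R6_gapR  gapR   - reads [ 5052, 5802)
```

The 16S product (1550 bp, inside the 1200–1700 bp acceptance window) and
the 23S product (2129 bp, inside 1800–2400 bp) confirm a complete operon in
the gap. The six reactions run in parallel — none depends on another's
read — and together with the already-known gene interiors they tile the
whole amplicon (`uncovered: none`): the flanks and the intragenic spacer
are resolved in a single sequencing round.

The end-to-end workflow on the bundled study-condition fixture
(`python examples/finish_draft.py`, scaled down to 1.2 Mb) prints:

```
contig trajectory: input=13 -> after_masking=9 -> after_placement=6
rDNA fragment ends: {'annotated_ends': 8, 'total_ends': 18}
N-stretches: 40
gap classifications: 4 of 5 gaps hold rDNA
rearrangement: insertion-at-N ~60 kb in contig_03
draft covered by final sequence: True
```

The working set shrinks as rRNA-only contigs are masked and small contigs
merge into their N-stretches; four of five gaps hold operons and get the
parallel plan; the planted 60 kb misassembly is recovered next to its
N-stretch; and the validation stage confirms the draft is fully contained
in the final sequence.

There is also a CLI mirroring each stage:

```bash
rdnafinish simulate --preset cr1-like --seed 42 -o fixture/
rdnafinish stats fixture/draft.fasta
rdnafinish insilico-pcr fixture/genome.fasta 8F 1492R
rdnafinish run-all fixture/draft.fasta --reference fixture/genome.fasta \
    --genes fixture/consensus_genes.fasta --pcr-template fixture/genome.fasta \
    -o run/
```

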