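"""Plan the six parallel sequencing reactions for an operon-containing gap.

Simulates a gap amplicon holding one complete 16S-ITS-23S-5S operon with
300 bp of unique flanking sequence, classifies it with the universal
primer pairs, and emits the parallel walk plan.
"""

from rdnafinish import classify_gap_rdna, generate_genome, plan_rdna_walk
from rdnafinish.gap_planner import GapPrimerPair
from rdnafinish.iupac import revcomp
from rdnafinish.primers import Primer

truth = generate_genome(size=1_200_000, operon_count=4, seed=11, margin=40_000)
o = truth.operons[0]
amplicon = truth.seq[o.start - 300 : o.end + 300]

cls = classify_gap_rdna("gap", amplicon, truth.consensus_genes())
print(f"amplicon {len(amplicon)} bp | 16S product {cls.product_16s} bp | "
      f"23S product {cls.product_23s} bp | 5S present: {cls.has_5s}")

pair = GapPrimerPair("gap", Primer("gapF", amplicon[:20]),
                     Primer("gapR", revcomp(amplicon[-20:])), 300, 300)
plan = plan_rdna_walk("gap", amplicon, pair, truth.consensus_genes())
print(f"strategy {plan.strategy}: {len(plan.reactions)} reactions, "
      f"work of {plan.stage_equivalent} serial walking stages, "
      f"uncovered: {plan.uncovered or 'none'}")
for r in plan.reactions:
    print(f"  {r.reaction_id:<8} {r.primer.name:<6} {r.direction} "
          f"reads [{r.read_start:>5},{r.read_end:>5})")
# All six reactions run in parallel (no reaction depends on another's read),
# tiling the unknown flanks and the 16S/23S intragenic spacer; the gene
# interiors are already known from the consensus sequences.
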