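"""Census the rRNA operons of a genome with consensus subunit genes.

Builds a small synthetic genome carrying four divergent rDNA operons,
scans it with the 16S/23S/5S consensus genes, and clusters the hits into
operon calls.
"""

from rdnafinish import Contig, cluster_operons, generate_genome, scan_contigs

truth = generate_genome(size=1_200_000, operon_count=4, divergence=0.02, seed=11,
                        margin=40_000)
hits = scan_contigs([Contig("genome", truth.seq)], truth.consensus_genes())
operons = cluster_operons(hits)

print(f"gene hits: {len(hits)}  operons: {len(operons)}")
for op in operons:
    print(f"  {op.start:>9,}-{op.end:<9,} strand {op.strand} "
          f"genes {','.join(op.genes)} complete={op.complete}")
# Each line is one rRNA operon: its genomic span, strand, the subunit genes
# found in it, and whether both 16S and 23S are present (a complete operon,
# eligible for the parallel six-reaction walk).
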