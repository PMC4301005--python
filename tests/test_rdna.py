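"""Consensus building, rDNA scanning, masking, end annotation, operons."""

import numpy as np
import pytest

from rdnafinish.iupac import revcomp
from rdnafinish.rdna import (
    ConsensusGene,
    RdnaHit,
    annotate_contig_ends,
    build_consensus,
    cluster_operons,
    mask_rrna_contigs,
    scan_contigs,
)
from rdnafinish.seqio import Contig


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestBuildConsensus:
    def test_identical_copies_passthrough(self):
        seqs = ["ACGTACGTGGCC"] * 3
        assert build_consensus("16S", seqs).seq == seqs[0]

    def test_majority_base_wins(self):
        seqs = ["AAGT", "AAGT", "AGGT"]
        assert build_consensus("x", seqs).seq == "AAGT"

    def test_tie_emits_iupac_code(self):
        seqs = ["AACGTACGTT", "AACGTACGTT", "AGCGTACGTT", "AGCGTACGTT"]
        cons = build_consensus("x", seqs)
        assert cons.seq[1] == "R"  # {A,G} tie

    def test_length_compatible_inputs_align_first(self):
        base = "ACGTACGTACGTACGTACGTACGTACGT"
        with_del = base[:10] + base[12:]
        cons = build_consensus("x", [base, base, with_del])
        assert cons.seq == base

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_consensus("x", [])


def _smith_waterman(query, target, match=2, mismatch=-3, gap=-5):
    """Tiny independent local aligner; returns (t_start, t_end, score)."""
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        sub = np.where(
            np.frombuffer(target.encode(), np.uint8) == ord(query[i - 1]), match, mismatch
        )
        row = H[i - 1, :-1] + sub
        H[i, 1:] = np.maximum(row, 0)
        H[i, 1:] = np.maximum(H[i, 1:], H[i, :-1] + gap)
        H[i, 1:] = np.maximum(H[i, 1:], H[i - 1, 1:] + gap)
        H[i][H[i] < 0] = 0
    i, j = np.unravel_index(np.argmax(H), H.shape)
    score = H[i, j]
    end = j
    # crude traceback along best predecessors to find the target start
    while i > 0 and j > 0 and H[i, j] > 0:
        diag = H[i - 1, j - 1]
        up = H[i - 1, j]
        left = H[i, j - 1]
        if H[i, j] == left + gap:
            j -= 1
        elif H[i, j] == up + gap:
            i -= 1
        else:
            i -= 1
            j -= 1
    return j, end, int(score)


@pytest.fixture(scope="module")
def gene():
    rng = np.random.default_rng(20)
    return ConsensusGene("16S", _random_dna(rng, 1500))


class TestScanContigs:

    def test_planted_exact_copy(self, gene):
        rng = np.random.default_rng(21)
        contig = Contig("c", _random_dna(rng, 800) + gene.seq + _random_dna(rng, 800))
        (hit,) = scan_contigs([contig], [gene])
        assert hit.strand == "+"
        assert hit.identity == 100.0
        assert hit.gene_coverage >= 0.99
        assert abs(hit.start - 800) <= 5 and abs(hit.end - 2300) <= 5

    def test_planted_mutated_copy_found_above_threshold(self, gene):
        rng = np.random.default_rng(22)
        copy = bytearray(gene.seq.encode())
        pos = rng.choice(len(copy), size=len(copy) // 20, replace=False)  # 5%
        for p in pos:
            copy[p] = ord("ACGT"[(b"ACGT".index(copy[p]) + 1) % 4])
        contig = Contig("c", _random_dna(rng, 500) + copy.decode() + _random_dna(rng, 500))
        hits = scan_contigs([contig], [gene])
        assert hits and hits[0].identity >= 90.0

    def test_reverse_complement_copy_on_minus_strand(self, gene):
        rng = np.random.default_rng(23)
        contig = Contig("c", _random_dna(rng, 400) + revcomp(gene.seq) + _random_dna(rng, 400))
        (hit,) = scan_contigs([contig], [gene])
        assert hit.strand == "-"
        assert abs(hit.start - 400) <= 5

    def test_fragment_at_contig_end(self, gene):
        rng = np.random.default_rng(24)
        contig = Contig("c", _random_dna(rng, 3000) + gene.seq[:250])
        (hit,) = scan_contigs([contig], [gene])
        assert hit.end >= 3240 and hit.identity >= 95

    def test_below_min_fragment_ignored(self, gene):
        rng = np.random.default_rng(25)
        contig = Contig("c", _random_dna(rng, 3000) + gene.seq[:60])
        assert scan_contigs([contig], [gene]) == []

    def test_agrees_with_local_alignment_oracle(self, gene):
        rng = np.random.default_rng(26)
        for trial in range(3):
            frag = gene.seq[200:800]
            contig_seq = _random_dna(rng, 1200) + frag + _random_dna(rng, 1200)
            (hit,) = scan_contigs([Contig("c", contig_seq)], [gene])
            t_start, t_end, _score = _smith_waterman(frag, contig_seq)
            assert abs(hit.start - t_start) <= 10
            assert abs(hit.end - t_end) <= 10


def _hit(cid, gene, s, e, strand="+", ident=99.0, cov=0.5):
    return RdnaHit(cid, gene, s, e, strand, ident, cov)


class TestMasking:
    def test_short_fully_covered_contig_masked(self):
        c = Contig("c", "A" * 1500)
        classes, kept = mask_rrna_contigs([c], [_hit("c", "16S", 0, 1500)])
        assert classes[0].masked and kept == []

    def test_large_contig_retained_regardless_of_coverage(self):
        c = Contig("c", "A" * 3000)
        classes, kept = mask_rrna_contigs([c], [_hit("c", "16S", 0, 3000)])
        assert not classes[0].masked and kept == [c]

    def test_low_coverage_contig_retained(self):
        c = Contig("c", "A" * 1500)
        classes, kept = mask_rrna_contigs([c], [_hit("c", "16S", 0, 450)])
        assert not classes[0].masked and kept == [c]

    def test_boundary_is_strictly_below_length_threshold(self):
        c = Contig("c", "A" * 2000)
        classes, _ = mask_rrna_contigs([c], [_hit("c", "16S", 0, 2000)])
        assert not classes[0].masked

    def test_overlapping_hits_not_double_counted(self):
        c = Contig("c", "A" * 1000)
        hits = [_hit("c", "16S", 0, 500), _hit("c", "16S", 300, 700)]
        classes, _ = mask_rrna_contigs([c], hits)
        assert classes[0].rdna_fraction == pytest.approx(0.7)


class TestEndAnnotation:
    def test_hit_overlapping_five_prime_window(self):
        c = Contig("c", "A" * 10_000)
        classes, tally = annotate_contig_ends([c], [_hit("c", "16S", 0, 800)])
        assert classes["c"].five_prime and not classes["c"].three_prime
        assert tally == {"annotated_ends": 1, "total_ends": 2}

    def test_interior_hit_annotates_nothing(self):
        c = Contig("c", "A" * 10_000)
        classes, tally = annotate_contig_ends([c], [_hit("c", "16S", 4000, 5000)])
        assert not classes["c"].five_prime and not classes["c"].three_prime

    def test_total_ends_is_twice_contig_count(self):
        contigs = [Contig(f"c{i}", "ACGT" * 100) for i in range(28)]
        _classes, tally = annotate_contig_ends(contigs, [])
        assert tally["total_ends"] == 56


class TestClusterOperons:
    def test_complete_operon_grouped(self):
        hits = [
            _hit("g", "16S", 1000, 2500),
            _hit("g", "23S", 3000, 5900),
            _hit("g", "5S", 6000, 6116),
        ]
        (op,) = cluster_operons(hits)
        assert op.complete and op.genes == ("16S", "23S", "5S")
        assert (op.start, op.end) == (1000, 6116)

    def test_distant_hits_split(self):
        hits = [_hit("g", "16S", 0, 1500), _hit("g", "16S", 50_000, 51_500)]
        assert len(cluster_operons(hits)) == 2

    def test_opposite_strands_never_merge(self):
        hits = [_hit("g", "16S", 0, 1500), _hit("g", "23S", 2000, 4900, strand="-")]
        ops = cluster_operons(hits)
        assert len(ops) == 2 and not any(o.complete for o in ops)

    def test_twelve_planted_operons_recovered(self, genome_hits):
        ops = cluster_operons(genome_hits)
        assert len(ops) == 12
        assert all(o.complete for o in ops)

    def test_spans_disjoint_per_strand(self, genome_hits):
        ops = cluster_operons(genome_hits)
        for strand in "+-":
            spans = sorted((o.start, o.end) for o in ops if o.strand == strand)
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
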