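"""Gap classification and walk-plan construction."""

import numpy as np
import pytest

from rdnafinish.gap_planner import (
    GapPrimerPair,
    classify_gap_rdna,
    plan_rdna_walk,
    plan_traditional_walk,
)
from rdnafinish.iupac import revcomp
from rdnafinish.primers import Primer, find_primer_sites


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _operon_amplicon(truth, idx=0, flank=300):
    """Gap-amplicon analog: full operon plus unique genomic flanks."""
    o = truth.operons[idx]
    return truth.seq[o.start - flank : o.end + flank]


def _gap_pair(amplicon):
    return GapPrimerPair(
        "gap", Primer("gapF", amplicon[:20]), Primer("gapR", revcomp(amplicon[-20:])), 300, 300
    )


class TestClassification:
    def test_full_operon_detected(self, cr1, cr1_genes):
        truth, _ = cr1
        cls = classify_gap_rdna("g", _operon_amplicon(truth), cr1_genes)
        assert cls.has_16s and cls.has_23s and cls.has_5s
        assert 1200 <= cls.product_16s <= 1700
        assert 1800 <= cls.product_23s <= 2400

    def test_rdna_free_amplicon_all_absent(self, cr1, cr1_genes):
        truth, _ = cr1
        # unique genomic sequence far from any operon
        o0, o1 = truth.operons[0], truth.operons[1]
        mid = (o0.end + o1.start) // 2
        cls = classify_gap_rdna("g", truth.seq[mid : mid + 8000], cr1_genes)
        assert not cls.has_16s and not cls.has_23s and not cls.has_5s

    def test_16s_only_amplicon(self, cr1, cr1_genes):
        truth, _ = cr1
        o = truth.operons[0]
        s16 = o.genes["16S"]
        amp = truth.seq[s16[0] - 200 : s16[1] + 100]
        cls = classify_gap_rdna("g", amp, cr1_genes)
        assert cls.has_16s and not cls.has_23s

    def test_without_5s_gene_supplied_5s_unknown(self, cr1):
        truth, _ = cr1
        cls = classify_gap_rdna("g", _operon_amplicon(truth), genes=None)
        assert cls.has_5s is None and cls.has_16s


class TestParallelWalk:
    def test_six_reactions_three_stages_full_coverage(self, cr1, cr1_genes):
        truth, _ = cr1
        amp = _operon_amplicon(truth)
        plan = plan_rdna_walk("gap", amp, _gap_pair(amp), cr1_genes)
        assert plan.strategy == "rdna-parallel"
        assert len(plan.reactions) == 6
        assert plan.stage_equivalent == 3
        assert plan.uncovered == []
        assert plan.degraded_segments == []

    def test_no_inter_reaction_dependencies(self, cr1, cr1_genes):
        truth, _ = cr1
        amp = _operon_amplicon(truth)
        plan = plan_rdna_walk("gap", amp, _gap_pair(amp), cr1_genes)
        assert all(r.depends_on is None for r in plan.reactions)

    def test_reads_plus_known_genes_cover_template(self, cr1, cr1_genes):
        from rdnafinish.rdna import scan_contigs
        from rdnafinish.seqio import Contig

        truth, _ = cr1
        amp = _operon_amplicon(truth)
        plan = plan_rdna_walk("gap", amp, _gap_pair(amp), cr1_genes)
        assert plan.uncovered == []
        intervals = [(r.read_start, r.read_end) for r in plan.reactions]
        for r in plan.reactions:
            L = len(r.primer.seq)
            if r.direction == "+":
                intervals.append((r.read_start - L, r.read_start))
            else:
                intervals.append((r.read_end, r.read_end + L))
        intervals += [
            (h.start, h.end) for h in scan_contigs([Contig("a", amp)], cr1_genes)
        ]
        intervals.sort()
        pos = 0
        for s, e in intervals:
            assert s <= pos, f"gap before {s}"
            pos = max(pos, e)
        assert pos >= len(amp)

    def test_oversized_intragenic_spacer_leaves_uncovered_interval(self, cr1, cr1_genes):
        rng = np.random.default_rng(50)
        truth, _ = cr1
        o = truth.operons[0]
        g16 = truth.seq[o.genes["16S"][0] : o.genes["16S"][1]]
        g23 = truth.seq[o.genes["23S"][0] : o.genes["23S"][1]]
        flank_l = truth.seq[o.start - 300 : o.start]
        flank_r = truth.seq[o.end : o.end + 300]
        its = _random_dna(rng, 2500)  # pathological spacer
        amp = flank_l + g16 + its + g23 + flank_r
        plan = plan_rdna_walk("gap", amp, _gap_pair(amp), cr1_genes)
        its_lo = 300 + len(g16)
        its_hi = its_lo + 2500
        assert any(its_lo < s and e < its_hi for s, e in plan.uncovered)

    def test_knocked_out_u2_site_degrades_segment(self, cr1, cr1_genes):
        from rdnafinish.primers import UNIVERSAL_PRIMERS

        truth, _ = cr1
        amp = _operon_amplicon(truth)
        u2 = UNIVERSAL_PRIMERS["U2"][0]
        site = amp.find(u2)
        assert site > 0
        # plant 4 substitutions inside the U2 footprint
        broken = bytearray(amp.encode())
        for off in (2, 7, 12, 17):
            cur = chr(broken[site + off])
            broken[site + off] = ord({"A": "C", "C": "A", "G": "T", "T": "G"}[cur])
        plan = plan_rdna_walk("gap", broken.decode(), _gap_pair(amp), cr1_genes)
        assert len(plan.reactions) == 5
        assert any("U2" in d for d in plan.degraded_segments)

    def test_amplicon_without_operon_rejected(self, cr1, cr1_genes):
        truth, _ = cr1
        o0, o1 = truth.operons[0], truth.operons[1]
        mid = (o0.end + o1.start) // 2
        with pytest.raises(ValueError, match="complete operon"):
            plan_rdna_walk("gap", truth.seq[mid : mid + 6000],
                           _gap_pair(truth.seq[mid : mid + 6000]), cr1_genes)


class TestTraditionalWalk:
    @pytest.mark.parametrize(
        "gap_length,stages,reactions",
        [(1500, 1, 2), (7500, 5, 10), (700, 1, 2), (1501, 2, 4)],
    )
    def test_stage_arithmetic(self, gap_length, stages, reactions):
        plan = plan_traditional_walk("g", gap_length)
        assert plan.strategy == "traditional"
        assert plan.stage_equivalent == stages
        assert len(plan.reactions) == reactions

    def test_dependency_chain(self):
        plan = plan_traditional_walk("g", 7500)
        by_id = {r.reaction_id: r for r in plan.reactions}
        first = [r for r in plan.reactions if r.depends_on is None]
        assert len(first) == 2  # one forward, one reverse entry point
        for r in plan.reactions:
            if r.depends_on is not None:
                assert r.depends_on in by_id

    def test_zero_gap_rejected(self):
        with pytest.raises(ValueError):
            plan_traditional_walk("g", 0)
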