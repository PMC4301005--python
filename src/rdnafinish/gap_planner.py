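"""Gap closure planning: gap-spanning primers, rDNA classification of gap
amplicons, and the parallel six-reaction rDNA walk plan.

The central idea: rRNA operons are the repeat that breaks short-read
assemblies, so most inter-contig gaps contain one. Because the 16S and 23S
genes are conserved, universal primers (8F/1492R and 127F/2241R) tell you
*from the gap amplicon alone* whether an operon sits in the gap, and four
operon-walking primers (U1-U4, hybridizing at the 5'/3' ends of the 16S
and 23S genes) let all the unknown sequence around a complete operon —
both flanks and the 16S/23S intragenic spacer — be Sanger-sequenced in six
parallel reactions, the work equivalent of three serial stages of blind
primer walking.

Coverage accounting treats the 16S/23S gene interiors as known a priori
(consensus genes exist — that is what makes the strategy work); "uncovered"
means unknown template sequence reached by no predicted read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .primers import (
    UNIVERSAL_PRIMERS,
    Amplicon,
    Primer,
    PrimerConstraints,
    PrimerSite,
    Undesignable,
    UniquenessScope,
    design_primer,
    find_primer_sites,
    simulate_pcr,
)
from .rdna import ConsensusGene, scan_contigs
from .seqio import Contig

#: acceptance windows (bp) for the universal-pair products; they bracket the
#: canonical bacterial gene lengths (16S ~1.5 kb amplified near-full-length,
#: 23S interior ~2.1 kb between the 127/2241 positions)
SIXTEEN_S_PRODUCT = (1200, 1700)
TWENTYTHREE_S_PRODUCT = (1800, 2400)

#: Sanger read-span model (bp per reaction): conservative, optimistic
READ_SPAN = (750, 1000)


def universal_primer(name: str) -> Primer:
    seq, _gene, _direction = UNIVERSAL_PRIMERS[name]
    return Primer(name=name, seq=seq)


@dataclass(frozen=True)
class GapPrimerPair:
    gap_id: str
    forward: Primer
    reverse: Primer
    fwd_offset: int  # distance of the forward 5' base from the left contig's inward end
    rev_offset: int


@dataclass(frozen=True)
class GapClassification:
    gap_id: str
    has_16s: bool
    has_23s: bool
    has_5s: bool | None  # None when no 5S consensus was supplied
    product_16s: int | None
    product_23s: int | None

    @property
    def rdna_present(self) -> bool:
        return self.has_16s or self.has_23s or bool(self.has_5s)


@dataclass(frozen=True)
class SequencingReaction:
    reaction_id: str
    template_id: str
    primer: Primer
    direction: str
    read_start: int
    read_end: int
    read_end_optimistic: int  # signed extent under the 1 kb best case
    depends_on: str | None = None


@dataclass
class WalkPlan:
    gap_id: str
    strategy: str  # 'rdna-parallel' | 'traditional'
    reactions: list[SequencingReaction]
    stage_equivalent: int
    uncovered: list[tuple[int, int]] = field(default_factory=list)
    degraded_segments: list[str] = field(default_factory=list)


def design_gap_primers(
    gap_id: str,
    left_contig: Contig,
    left_orientation: str,
    right_contig: Contig,
    right_orientation: str,
    constraints: PrimerConstraints = PrimerConstraints(),
    scope: UniquenessScope | None = None,
    offset_range: tuple[int, int] = (250, 350),
) -> GapPrimerPair | Undesignable:
    """Primer pair reading into the gap, each 5' base 250-350 bp inside its
    contig's inward end, so the terminal (often repeat-bearing) sequence
    stays inside the amplicon while the primers sit in unique sequence.

    Contigs are taken in layout orientation: the left contig's inward end is
    its oriented 3' terminus, the right contig's its oriented 5' terminus.
    """
    from .iupac import revcomp

    lo, hi = offset_range
    lseq = left_contig.seq if left_orientation == "+" else revcomp(left_contig.seq)
    rseq = right_contig.seq if right_orientation == "+" else revcomp(right_contig.seq)
    if len(lseq) < hi or len(rseq) < hi:
        return Undesignable("contig terminal sequence shorter than the offset range")
    L = len(lseq)
    fwd = design_primer(
        lseq,
        window=(L - hi, L - lo + constraints.max_len),
        direction="+",
        constraints=constraints,
        scope=scope,
        name=f"{gap_id}F",
        five_prime_range=(L - hi, L - lo + 1),
    )
    if isinstance(fwd, Undesignable):
        return Undesignable(f"forward: {fwd.reason}", fwd.failures)
    rev = design_primer(
        rseq,
        window=(lo - constraints.max_len, hi + 1),
        direction="-",
        constraints=constraints,
        scope=scope,
        name=f"{gap_id}R",
        five_prime_range=(lo, hi + 1),
    )
    if isinstance(rev, Undesignable):
        return Undesignable(f"reverse: {rev.reason}", rev.failures)
    fwd_off = L - lseq.find(fwd.seq)
    rev_off = rseq.find(revcomp(rev.seq)) + len(rev.seq)
    return GapPrimerPair(gap_id, fwd, rev, fwd_off, rev_off)


def classify_gap_rdna(
    gap_id: str,
    amplicon_seq: str,
    genes: list[ConsensusGene] | None = None,
) -> GapClassification:
    """Judge rDNA content of a gap amplicon with the universal primer pairs.

    16S is present when 8F/1492R yields an in-silico product of 1200-1700 bp,
    23S when 127F/2241R yields 1800-2400 bp; 5S (no universal pair exists) is
    assessed by direct consensus scan when a 5S gene is supplied.
    """
    if not amplicon_seq:
        raise ValueError("empty amplicon")
    prod16 = simulate_pcr(amplicon_seq, universal_primer("8F"), universal_primer("1492R"))
    p16 = next((p.length for p in prod16 if SIXTEEN_S_PRODUCT[0] <= p.length <= SIXTEEN_S_PRODUCT[1]), None)
    prod23 = simulate_pcr(amplicon_seq, universal_primer("127F"), universal_primer("2241R"))
    p23 = next((p.length for p in prod23 if TWENTYTHREE_S_PRODUCT[0] <= p.length <= TWENTYTHREE_S_PRODUCT[1]), None)
    has5: bool | None = None
    if genes is not None:
        five = [g for g in genes if g.name == "5S"]
        if five:
            hits = scan_contigs([Contig("amplicon", amplicon_seq)], five)
            has5 = bool(hits)
    return GapClassification(
        gap_id=gap_id,
        has_16s=p16 is not None,
        has_23s=p23 is not None,
        has_5s=has5,
        product_16s=p16,
        product_23s=p23,
    )


def _site_in(sites: list[PrimerSite], strand: str, lo: int, hi: int) -> PrimerSite | None:
    """Best (fewest-mismatch) site on ``strand`` whose start lies in [lo, hi)."""
    best = None
    for s in sites:
        if s.strand == strand and lo <= s.start < hi:
            if best is None or s.mismatches < best.mismatches:
                best = s
    return best


def _reaction(
    rid: str, template_id: str, primer: Primer, site: PrimerSite, template_len: int,
    depends_on: str | None = None,
) -> SequencingReaction:
    cons, opt = READ_SPAN
    if site.strand == "+":
        start = site.end
        end = min(template_len, start + cons)
        end_opt = min(template_len, start + opt)
    else:
        end = site.start
        start = max(0, end - cons)
        end_opt = max(0, end - opt)
        return SequencingReaction(rid, template_id, primer, "-", start, end, end_opt, depends_on)
    return SequencingReaction(rid, template_id, primer, "+", start, end, end_opt, depends_on)


def _subtract(intervals: list[tuple[int, int]], total: tuple[int, int]) -> list[tuple[int, int]]:
    """Portions of ``total`` not covered by ``intervals``."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        s, e = max(s, total[0]), min(e, total[1])
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    pos = total[0]
    for s, e in merged:
        if s > pos:
            out.append((pos, s))
        pos = e
    if pos < total[1]:
        out.append((pos, total[1]))
    return out


def plan_rdna_walk(
    gap_id: str,
    amplicon_seq: str,
    gap_pair: GapPrimerPair,
    genes: list[ConsensusGene],
    template_id: str | None = None,
) -> WalkPlan:
    """The parallel six-reaction plan for a gap amplicon holding a complete
    operon: gap-forward into the left flank, U1 back across the left flank,
    U2/U3 bidirectionally across the intragenic spacer, U4 into the right
    flank, gap-reverse back across it. All six run in parallel — the work
    equivalent of three serial primer-walking stages.

    A universal primer without a usable site degrades its segment to
    traditional walking, recorded in ``degraded_segments``.
    """
    template_id = template_id or f"{gap_id}_amplicon"
    n = len(amplicon_seq)
    hits = scan_contigs([Contig(template_id, amplicon_seq)], genes)
    g16 = next((h for h in hits if h.gene == "16S"), None)
    g23 = next((h for h in hits if h.gene == "23S"), None)
    if g16 is None or g23 is None:
        raise ValueError(
            f"gap {gap_id}: amplicon does not contain a complete operon; "
            "use plan_traditional_walk"
        )
    reactions: list[SequencingReaction] = []
    degraded: list[str] = []

    # gap primers anchor the template ends
    fsites = find_primer_sites(amplicon_seq, gap_pair.forward, template_id=template_id)
    fsite = _site_in(fsites, "+", 0, max(1, n // 4))
    rsites = find_primer_sites(amplicon_seq, gap_pair.reverse, template_id=template_id)
    rsite = _site_in(rsites, "-", 3 * n // 4, n)
    if fsite:
        reactions.append(_reaction("R1_gapF", template_id, gap_pair.forward, fsite, n))
    else:
        degraded.append("left-flank entry (gap forward primer has no site)")
    mid16 = (g16.start + g16.end) // 2
    mid23 = (g23.start + g23.end) // 2
    expectations = [
        ("R2_U1", "U1", "-", g16.start - 50, mid16, "16S-5' back into left flank"),
        ("R3_U2", "U2", "+", mid16, g16.end + 50, "16S-3' across the intragenic region"),
        ("R4_U3", "U3", "-", g23.start - 50, mid23, "23S-5' back across the intragenic region"),
        ("R5_U4", "U4", "+", mid23, g23.end + 50, "23S-3' into the right flank"),
    ]
    for rid, uname, strand, lo, hi, label in expectations:
        primer = universal_primer(uname)
        site = _site_in(find_primer_sites(amplicon_seq, primer, template_id=template_id), strand, lo, hi)
        if site is None:
            degraded.append(f"{label} ({uname} has no site)")
            continue
        reactions.append(_reaction(rid, template_id, primer, site, n))
    if rsite:
        reactions.append(_reaction("R6_gapR", template_id, gap_pair.reverse, rsite, n))
    else:
        degraded.append("right-flank entry (gap reverse primer has no site)")

    known: list[tuple[int, int]] = [(g16.start, g16.end), (g23.start, g23.end)]
    g5 = next((h for h in hits if h.gene == "5S"), None)
    if g5:
        known.append((g5.start, g5.end))
    covered = known + [(r.read_start, r.read_end) for r in reactions]
    for r in reactions:
        site_span = (
            (r.read_end, r.read_end + len(r.primer.seq))
            if r.direction == "-"
            else (r.read_start - len(r.primer.seq), r.read_start)
        )
        covered.append(site_span)
    uncovered = _subtract(covered, (0, n))
    return WalkPlan(
        gap_id=gap_id,
        strategy="rdna-parallel",
        reactions=reactions,
        stage_equivalent=math.ceil(len(reactions) / 2),
        uncovered=uncovered,
        degraded_segments=degraded,
    )


def plan_traditional_walk(gap_id: str, gap_length: int) -> WalkPlan:
    """Serial bidirectional primer walking: each stage's primers depend on
    the previous stage's reads; ~750 bp (conservative) readable per run."""
    if gap_length <= 0:
        raise ValueError("gap length must be positive")
    cons, opt = READ_SPAN
    stages = math.ceil(gap_length / (2 * cons))
    reactions: list[SequencingReaction] = []
    for s in range(stages):
        dep_f = f"{gap_id}_s{s}F" if s else None
        dep_r = f"{gap_id}_s{s}R" if s else None
        f_start = s * cons
        r_end = max(0, gap_length - s * cons)
        reactions.append(
            SequencingReaction(
                f"{gap_id}_s{s + 1}F", gap_id, Primer(f"{gap_id}_s{s + 1}F_tbd", "N" * 20),
                "+", f_start, min(gap_length, f_start + cons),
                min(gap_length, f_start + opt), depends_on=dep_f,
            )
        )
        reactions.append(
            SequencingReaction(
                f"{gap_id}_s{s + 1}R", gap_id, Primer(f"{gap_id}_s{s + 1}R_tbd", "N" * 20),
                "-", max(0, r_end - cons), r_end,
                max(0, r_end - opt), depends_on=dep_r,
            )
        )
    return WalkPlan(
        gap_id=gap_id,
        strategy="traditional",
        reactions=reactions,
        stage_equivalent=stages,
        uncovered=[],
    )
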