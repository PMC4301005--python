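"""rDNA gene detection: consensus building, contig scanning, rRNA-contig
masking, contig-end annotation, and operon clustering.

The multi-copy 16S-ITS-23S(-5S) operon is the dominant repeat breaking
short-read bacterial assemblies: whole operons land in inter-contig gaps,
gene fragments accumulate at contig boundaries, and short chimeric
"isoform" contigs assemble entirely from rRNA reads. The operations here
locate those signatures with consensus subunit genes.

Scanning is seed-and-extend: exact gene k-mers (k=13) identify candidate
windows, which are then aligned with edlib (unit-cost edit distance,
IUPAC-aware via additional equalities) to produce identity and coverage.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .iupac import IUPAC_SETS, kmer_codes, revcomp
from .seqio import Contig

#: expected subunit gene length ranges (bp)
GENE_LENGTH_RANGES = {"16S": (1400, 1600), "23S": (2700, 3100), "5S": (100, 130)}

#: edlib equality pairs so consensus ambiguity codes match concrete bases
_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC_SETS.items()
    if len(bases) > 1
    for base in bases
]

_SEED_K = 13


@dataclass(frozen=True)
class ConsensusGene:
    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RdnaHit:
    contig_id: str
    gene: str
    start: int
    end: int
    strand: str
    identity: float  # percent
    gene_coverage: float  # fraction of gene length aligned


@dataclass(frozen=True)
class EndAnnotation:
    gene: str
    start: int
    end: int


@dataclass
class ContigClass:
    contig_id: str
    length: int
    masked: bool
    rdna_fraction: float
    five_prime: list[EndAnnotation] = field(default_factory=list)
    three_prime: list[EndAnnotation] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class OperonCall:
    seq_id: str
    start: int
    end: int
    strand: str
    genes: tuple[str, ...]
    complete: bool  # has both 16S and 23S
    hits: tuple[RdnaHit, ...]


def _iupac_tie_code(bases: frozenset[str]) -> str:
    from .iupac import SETS_TO_CODE

    return SETS_TO_CODE[bases]


def build_consensus(name: str, copies: list[str]) -> ConsensusGene:
    """Per-column majority consensus of near-identical gene copies.

    The longest copy serves as the column frame; the others are mapped onto
    it by edit-distance alignment. Ties emit the IUPAC code covering the
    tied bases; columns where gaps hold the majority are dropped.
    """
    if not copies:
        raise ValueError("build_consensus needs at least one sequence")
    copies = [c.upper().replace("U", "T") for c in copies]
    if len(copies) == 1:
        return ConsensusGene(name=name, seq=copies[0])
    ref = max(copies, key=len)
    # columns[i] = bases aligned to ref position i; insertions relative to
    # the frame are rare in near-identical copies and are dropped.
    columns: list[list[str]] = [[] for _ in range(len(ref))]
    for seq in copies:
        if seq == ref:
            for i, ch in enumerate(seq):
                columns[i].append(ch)
            continue
        aln = edlib.align(seq, ref, task="path", mode="NW")
        qi = ri = 0
        for n, op in _cigar_ops(aln["cigar"]):
            if op in "=XM":
                for j in range(n):
                    columns[ri + j].append(seq[qi + j])
                qi += n
                ri += n
            elif op == "I":  # insertion in query relative to frame
                qi += n
            elif op == "D":  # deletion in query: gap characters
                for j in range(n):
                    columns[ri + j].append("-")
                ri += n
    out = []
    half = len(copies) / 2
    for col in columns:
        gaps = col.count("-")
        if gaps > half:
            continue
        counts: dict[str, int] = defaultdict(int)
        for ch in col:
            if ch != "-":
                counts[ch] += 1
        top = max(counts.values())
        winners = frozenset(b for base in counts if counts[base] == top for b in IUPAC_SETS[base])
        if sum(1 for c in counts.values() if c == top) == 1:
            out.append(next(b for b in counts if counts[b] == top))
        else:
            out.append(_iupac_tie_code(winners))
    return ConsensusGene(name=name, seq="".join(out))


def _cigar_ops(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def _trimmed_alignment(cigar: str) -> tuple[float, int, int, int, int]:
    """Soft-clip the ends of an edit alignment and summarize it.

    edlib's infix mode consumes the whole query, so a query extending past
    the true fragment boundary accumulates terminal edits. The alignment is
    clipped to its maximum-scoring subsegment before computing identity.

    Returns (identity fraction, query aligned length, target leading offset,
    target aligned length, query leading offset), all for the clipped span.
    """
    ops: list[str] = []
    for n, op in _cigar_ops(cigar):
        ops.extend(op * n)
    # maximum-scoring subsegment of the column score sequence; edits are
    # penalized 3:1 because edit-optimal alignment of unrelated sequence
    # still matches ~2/3 of columns via free indels
    best, best_start, best_end = 0, 0, 0
    run, run_start = 0, 0
    for i, op in enumerate(ops):
        run += 1 if op == "=" else -3
        if run <= 0:
            run, run_start = 0, i + 1
        elif run > best:
            best, best_start, best_end = run, run_start, i + 1
    start, end = best_start, best_end
    if start >= end:
        return 0.0, 0, 0, 0, 0
    clipped = ops[start:end]
    matches = clipped.count("=")
    q_len = sum(1 for o in clipped if o in "=XMI")
    t_len = sum(1 for o in clipped if o in "=XMD")
    t_off = sum(1 for o in ops[:start] if o in "=XMD")
    q_off = sum(1 for o in ops[:start] if o in "=XMI")
    return matches / len(clipped), q_len, t_off, t_len, q_off


def _candidate_windows(gene_seq: str, target: str) -> list[tuple[int, int, int, int]]:
    """Cluster exact k-mer seed matches into candidate alignment windows.

    Returns (t_lo, t_hi, q_lo, q_hi) per cluster in target coordinates.
    """
    gcodes, gstarts = kmer_codes(gene_seq, _SEED_K)
    if len(gcodes) == 0:
        return []
    # only k-mers unique within the gene seed unambiguous diagonals
    uniq, first_idx, counts = np.unique(gcodes, return_index=True, return_counts=True)
    keep = counts == 1
    gsorted = uniq[keep]
    gpos_sorted = gstarts[first_idx[keep]]
    tcodes, tstarts = kmer_codes(target, _SEED_K)
    if len(tcodes) == 0 or len(gsorted) == 0:
        return []
    idx = np.searchsorted(gsorted, tcodes)
    idx[idx == len(gsorted)] = 0
    hitmask = gsorted[idx] == tcodes
    tpos = tstarts[hitmask]
    qpos = gpos_sorted[idx[hitmask]]
    if len(tpos) == 0:
        return []
    # cluster by diagonal (anchored to the cluster's first seed, so noisy
    # seeds cannot chain-drift the diagonal) then by target position
    diag = tpos - qpos
    order2 = np.lexsort((tpos, diag))
    tpos, qpos, diag = tpos[order2], qpos[order2], diag[order2]
    clusters: list[list[int]] = []
    cur: list[int] = [0]
    for i in range(1, len(tpos)):
        if abs(int(diag[i]) - int(diag[cur[0]])) <= 150 and tpos[i] - tpos[cur[-1]] <= 2000:
            cur.append(i)
        else:
            clusters.append(cur)
            cur = [i]
    clusters.append(cur)
    # merge clusters that overlap in target space (different diagonals of one locus)
    raw = []
    for cl in clusters:
        ts = int(tpos.take(cl).min())
        te = int(tpos.take(cl).max()) + _SEED_K
        qs = int(qpos.take(cl).min())
        qe = int(qpos.take(cl).max()) + _SEED_K
        raw.append((ts, te, qs, qe, len(cl)))
    raw.sort()
    merged: list[list[int]] = []
    for ts, te, qs, qe, n in raw:
        if merged and ts <= merged[-1][1] + 100:
            merged[-1][1] = max(merged[-1][1], te)
            merged[-1][2] = min(merged[-1][2], qs)
            merged[-1][3] = max(merged[-1][3], qe)
            merged[-1][4] += n
        else:
            merged.append([ts, te, qs, qe, n])
    return [(a, b, c, d) for a, b, c, d, n in merged if n >= 2 or d - c >= 2 * _SEED_K]


def _align_fragment(
    gene: ConsensusGene, target: str, window: tuple[int, int, int, int], max_div: float
) -> tuple[int, int, float, float] | None:
    """edlib-align the seeded gene portion into the seeded target window.

    Returns (t_start, t_end, identity%, gene_coverage) or None.
    """
    t_lo, t_hi, q_lo, q_hi = window
    ext = 100
    # the query must fit inside the target window (infix alignment): extend
    # the query only as far as the target has room on each side
    q_lo = max(0, q_lo - min(ext, t_lo + 25))
    q_hi = min(gene.length, q_hi + min(ext, len(target) - t_hi + 25))
    t_lo = max(0, t_lo - ext - 50)
    t_hi = min(len(target), t_hi + ext + 50)
    query = gene.seq[q_lo:q_hi]
    sub = target[t_lo:t_hi]
    if not query or not sub:
        return None
    k = int(len(query) * max_div * 2) + 60
    aln = edlib.align(query, sub, task="path", mode="HW", k=k,
                      additionalEqualities=_EQUALITIES)
    if aln["editDistance"] < 0:
        return None
    ident, q_len, t_off, t_len, _q_off = _trimmed_alignment(aln["cigar"])
    loc = aln["locations"][0]
    start = t_lo + loc[0] + t_off
    return start, start + t_len, 100.0 * ident, q_len / gene.length


def _merge_hits(hits: list[RdnaHit]) -> list[RdnaHit]:
    """Merge overlapping same-gene same-strand hits, keeping best identity."""
    out: list[RdnaHit] = []
    for h in sorted(hits, key=lambda h: (h.gene, h.strand, h.start)):
        if (
            out
            and out[-1].gene == h.gene
            and out[-1].strand == h.strand
            and h.start < out[-1].end
        ):
            prev = out[-1]
            out[-1] = RdnaHit(
                prev.contig_id,
                prev.gene,
                min(prev.start, h.start),
                max(prev.end, h.end),
                prev.strand,
                max(prev.identity, h.identity),
                min(1.0, max(prev.gene_coverage, h.gene_coverage)),
            )
        else:
            out.append(h)
    out.sort(key=lambda h: (h.start, h.end))
    return out


def scan_contigs(
    contigs: list[Contig],
    genes: list[ConsensusGene],
    min_identity: float = 90.0,
    min_fragment: int = 100,
) -> list[RdnaHit]:
    """Locate subunit-gene fragments on both strands of every contig.

    Hits with identity >= ``min_identity`` percent over an aligned length of
    at least ``min_fragment`` bp are reported; overlapping hits of the same
    gene are merged keeping the best identity.
    """
    if not genes:
        raise ValueError("scan_contigs needs at least one consensus gene")
    max_div = 1.0 - min_identity / 100.0
    all_hits: list[RdnaHit] = []
    for contig in contigs:
        hits: list[RdnaHit] = []
        for strand in "+-":
            seq = contig.seq if strand == "+" else revcomp(contig.seq)
            for gene in genes:
                for win in _candidate_windows(gene.seq, seq):
                    res = _align_fragment(gene, seq, win, max_div)
                    if res is None:
                        continue
                    s, e, ident, cov = res
                    if ident < min_identity or (e - s) < min_fragment:
                        continue
                    if strand == "-":
                        s, e = len(seq) - e, len(seq) - s
                    hits.append(
                        RdnaHit(contig.id, gene.name, s, e, strand, round(ident, 2), round(cov, 4))
                    )
        all_hits.extend(_merge_hits(hits))
    return all_hits


def _covered_fraction(length: int, intervals: list[tuple[int, int]]) -> float:
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / length


def mask_rrna_contigs(
    contigs: list[Contig],
    hits: list[RdnaHit],
    max_length: int = 2000,
    min_covered: float = 0.8,
) -> tuple[list[ContigClass], list[Contig]]:
    """Flag and set aside short contigs comprised essentially of rRNA genes.

    A contig is masked when it is shorter than ``max_length`` bp AND its
    rDNA-covered fraction is at least ``min_covered``; everything else is
    returned unchanged in the working set.
    """
    by_contig: dict[str, list[RdnaHit]] = defaultdict(list)
    for h in hits:
        by_contig[h.contig_id].append(h)
    report: list[ContigClass] = []
    kept: list[Contig] = []
    for c in contigs:
        ch = by_contig.get(c.id, [])
        frac = _covered_fraction(c.length, [(h.start, h.end) for h in ch])
        masked = c.length < max_length and frac >= min_covered
        report.append(
            ContigClass(
                contig_id=c.id,
                length=c.length,
                masked=masked,
                rdna_fraction=round(frac, 4),
                genes=sorted({h.gene for h in ch}),
            )
        )
        if not masked:
            kept.append(c)
    return report, kept


def annotate_contig_ends(
    contigs: list[Contig],
    hits: list[RdnaHit],
    end_window: int = 200,
) -> tuple[dict[str, ContigClass], dict[str, int]]:
    """Annotate contig termini carrying rDNA fragments.

    An end is annotated with gene g when a hit for g starts or ends within
    ``end_window`` bp of that terminus. Returns per-contig classes plus a
    tally {annotated_ends, total_ends}.
    """
    by_contig: dict[str, list[RdnaHit]] = defaultdict(list)
    for h in hits:
        by_contig[h.contig_id].append(h)
    classes: dict[str, ContigClass] = {}
    annotated = 0
    for c in contigs:
        cls = ContigClass(contig_id=c.id, length=c.length, masked=False, rdna_fraction=0.0)
        for h in by_contig.get(c.id, []):
            ann = EndAnnotation(h.gene, h.start, h.end)
            if h.start < end_window or h.end <= end_window:
                cls.five_prime.append(ann)
            if h.end > c.length - end_window or h.start >= c.length - end_window:
                cls.three_prime.append(ann)
        annotated += bool(cls.five_prime) + bool(cls.three_prime)
        classes[c.id] = cls
    tally = {"annotated_ends": annotated, "total_ends": 2 * len(contigs)}
    return classes, tally


def cluster_operons(
    hits: list[RdnaHit],
    max_span: int = 10_000,
) -> list[OperonCall]:
    """Group same-strand gene hits on one sequence into operon calls.

    Consecutive hits join the current operon while the running span stays
    within ``max_span``; an operon is complete when it contains both 16S
    and 23S.
    """
    calls: list[OperonCall] = []
    for strand in "+-":
        strand_hits = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: h.start
        )
        group: list[RdnaHit] = []
        for h in strand_hits:
            if group and (h.end - group[0].start) > max_span:
                calls.append(_make_call(group))
                group = []
            group.append(h)
        if group:
            calls.append(_make_call(group))
    calls.sort(key=lambda c: c.start)
    return calls


def _make_call(group: list[RdnaHit]) -> OperonCall:
    genes = tuple(sorted({h.gene for h in group}))
    return OperonCall(
        seq_id=group[0].contig_id,
        start=min(h.start for h in group),
        end=max(h.end for h in group),
        strand=group[0].strand,
        genes=genes,
        complete=("16S" in genes and "23S" in genes),
        hits=tuple(group),
    )
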