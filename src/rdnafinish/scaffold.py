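"""Reference-guided contig ordering and orientation via unique-k-mer anchors.

A deliberately simple, deterministic stand-in for whole-genome-aligner
contig reordering: maximal exact matches are seeded from k-mers that occur
exactly once in the reference and once in the contig set, so repeat regions
(rDNA operons above all) anchor poorly by design — exactly the regions
where short-read assemblies break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .iupac import kmer_codes, revcomp
from .seqio import Contig


@dataclass(frozen=True)
class Anchor:
    contig_id: str
    c_start: int
    c_end: int
    r_start: int
    r_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.c_end - self.c_start


@dataclass(frozen=True)
class Placement:
    contig_id: str
    orientation: str
    ref_start: int  # projected reference coordinate of the oriented 5' end
    anchored_bases: int
    tie_warning: bool = False


@dataclass
class ScaffoldLayout:
    placed: list[Placement]
    unplaced: list[str]


@dataclass
class GapRecord:
    left_id: str
    right_id: str
    size: int  # may be negative: putative overlap
    overlap: bool
    rdna: str = "unknown"  # unknown | present | absent
    genes: tuple[str, ...] = ()


class ReferenceIndex:
    """Sorted unique-k-mer index of a reference sequence."""

    def __init__(self, reference: str, k: int = 21) -> None:
        self.k = k
        self.length = len(reference)
        self.seq = reference
        codes, starts = kmer_codes(reference, k)
        rc_codes, _ = kmer_codes(revcomp(reference), k)
        # a k-mer is usable only if it occurs exactly once across both strands
        allc = np.concatenate([codes, rc_codes])
        uniq, counts = np.unique(allc, return_counts=True)
        once = uniq[counts == 1]
        mask = _member(once, codes)
        order = np.argsort(codes[mask], kind="stable")
        self.codes = codes[mask][order]
        self.starts = starts[mask][order]

    def lookup(self, codes: np.ndarray, starts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query_start, ref_start) pairs for query k-mers present in the index."""
        if len(codes) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        idx = np.searchsorted(self.codes, codes)
        idx[idx == len(self.codes)] = 0
        hit = self.codes.size > 0
        m = (self.codes[idx] == codes) if hit else np.zeros(len(codes), bool)
        return starts[m], self.starts[idx[m]]


def _unique_codes(codes: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(codes, return_counts=True)
    return uniq[counts == 1]


def _member(sorted_ref: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Membership of ``values`` in a sorted array (boolean mask)."""
    if len(sorted_ref) == 0 or len(values) == 0:
        return np.zeros(len(values), dtype=bool)
    idx = np.searchsorted(sorted_ref, values)
    idx[idx == len(sorted_ref)] = 0
    return sorted_ref[idx] == values


def _collapse_seed_runs(
    qpos: np.ndarray, rpos: np.ndarray, k: int
) -> list[tuple[int, int]]:
    """One representative seed per maximal same-diagonal run.

    Seeds from one exact match lie consecutively on a diagonal; extending
    from the first is enough, so runs are collapsed before the (python)
    extension loop.
    """
    if len(qpos) == 0:
        return []
    diag = rpos - qpos
    order = np.lexsort((qpos, diag))
    q, r, d = qpos[order], rpos[order], diag[order]
    new_run = np.ones(len(q), dtype=bool)
    new_run[1:] = (np.diff(d) != 0) | (np.diff(q) > k)
    starts = np.nonzero(new_run)[0]
    return [(int(q[i]), int(r[i])) for i in starts]


def _extend_match(a: str, b: str, ai: int, bi: int, direction: int) -> int:
    """Number of matching characters walking from a[ai]/b[bi] in direction."""
    n = 0
    step = 4096
    while True:
        if direction > 0:
            sa = a[ai + n : ai + n + step]
            sb = b[bi + n : bi + n + step]
        else:
            sa = a[max(0, ai - n - step + 1) : ai - n + 1][::-1]
            sb = b[max(0, bi - n - step + 1) : bi - n + 1][::-1]
        if not sa or not sb:
            return n
        m = min(len(sa), len(sb))
        i = 0
        while i < m and sa[i] == sb[i]:
            i += 1
        n += i
        if i < m or m < step:
            return n


def anchor_contigs(
    contigs: list[Contig],
    reference: str | Contig,
    k: int = 21,
    index: ReferenceIndex | None = None,
) -> list[Anchor]:
    """Maximal exact matches seeded from k-mers unique in both the reference
    and the contig set; anchors shorter than 2k are discarded."""
    ref = reference.seq if isinstance(reference, Contig) else reference
    if not ref:
        raise ValueError("reference must be non-empty")
    idx = index if index is not None and index.k == k else ReferenceIndex(ref, k)

    # contig-set-wide uniqueness (canonical: forward + revcomp occurrences)
    all_codes = []
    for c in contigs:
        for s in (c.seq, revcomp(c.seq)):
            codes, _ = kmer_codes(s, k)
            all_codes.append(codes)
    set_unique = _unique_codes(np.concatenate(all_codes)) if all_codes else np.empty(0, np.uint64)

    anchors: list[Anchor] = []
    for contig in contigs:
        for strand in "+-":
            seq = contig.seq if strand == "+" else revcomp(contig.seq)
            codes, starts = kmer_codes(seq, k)
            keep = _member(set_unique, codes)
            qpos, rpos = idx.lookup(codes[keep], starts[keep])
            seen: set[tuple[int, int]] = set()
            for qi, ri in _collapse_seed_runs(qpos, rpos, k):
                left = _extend_match(seq, ref, qi - 1, ri - 1, -1)
                right = _extend_match(seq, ref, qi + k, ri + k, +1)
                qs, qe = qi - left, qi + k + right
                rs = ri - left
                if qe - qs < 2 * k:
                    continue
                if (qs, rs) in seen:
                    continue
                seen.add((qs, rs))
                if strand == "+":
                    cs, ce = qs, qe
                else:
                    cs, ce = len(seq) - qe, len(seq) - qs
                anchors.append(Anchor(contig.id, cs, ce, rs, rs + (qe - qs), strand))
    anchors.sort(key=lambda a: (a.contig_id, a.r_start))
    return anchors


def order_and_orient(contigs: list[Contig], anchors: list[Anchor]) -> ScaffoldLayout:
    """Order and orient contigs from their anchors.

    Orientation is the strand carrying the majority of anchored bases (exact
    tie -> '+', flagged); the reference start estimate projects the
    contig's oriented 5' end from the anchor nearest that end. Contigs
    without anchors are reported unplaced.
    """
    by_contig: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_contig.setdefault(a.contig_id, []).append(a)
    placed: list[Placement] = []
    unplaced: list[str] = []
    lengths = {c.id: c.length for c in contigs}
    for c in contigs:
        alist = by_contig.get(c.id)
        if not alist:
            unplaced.append(c.id)
            continue
        plus = sum(a.length for a in alist if a.strand == "+")
        minus = sum(a.length for a in alist if a.strand == "-")
        tie = plus == minus
        orientation = "+" if plus >= minus else "-"
        use = [a for a in alist if a.strand == orientation]
        # project the oriented 5' end from the anchor nearest that end: a
        # local projection, so internal structural differences (an inserted
        # misassembled block) cannot shift where the contig's first bases
        # actually sit on the reference
        if orientation == "+":
            near = min(use, key=lambda a: a.c_start)
            est = near.r_start - near.c_start
        else:
            near = max(use, key=lambda a: a.c_end)
            est = near.r_start - (lengths[c.id] - near.c_end)
        placed.append(
            Placement(
                contig_id=c.id,
                orientation=orientation,
                ref_start=int(est),
                anchored_bases=plus + minus,
                tie_warning=tie,
            )
        )
    placed.sort(key=lambda p: p.ref_start)
    return ScaffoldLayout(placed=placed, unplaced=unplaced)


def _oriented_anchors(
    anchors: list[Anchor], contig_len: int, orientation: str
) -> list[tuple[int, int, int, int]]:
    """Anchors as (o_start, o_end, r_start, r_end) in oriented contig
    coordinates, restricted to the layout orientation's strand."""
    out = []
    for a in anchors:
        if a.strand != orientation:
            continue
        if orientation == "+":
            out.append((a.c_start, a.c_end, a.r_start, a.r_end))
        else:
            out.append((contig_len - a.c_end, contig_len - a.c_start, a.r_start, a.r_end))
    return out


def estimate_gap_sizes(
    layout: ScaffoldLayout, contigs: list[Contig], anchors: list[Anchor]
) -> list[GapRecord]:
    """Reference-projected distance between the inward ends of adjacent
    placed contigs; negative values are flagged as putative overlaps.

    Each inward end is projected from the anchor closest to that end, which
    keeps the estimate local: internal structural differences elsewhere in a
    contig (a misassembled block, N-run length jitter) cannot shift it.
    """
    if len(layout.placed) < 2:
        raise ValueError("need at least two placed contigs to estimate gaps")
    lengths = {c.id: c.length for c in contigs}
    by_contig: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_contig.setdefault(a.contig_id, []).append(a)
    gaps: list[GapRecord] = []
    for left, right in zip(layout.placed, layout.placed[1:]):
        llen = lengths[left.contig_id]
        rlen = lengths[right.contig_id]
        la = _oriented_anchors(by_contig.get(left.contig_id, []), llen, left.orientation)
        ra = _oriented_anchors(by_contig.get(right.contig_id, []), rlen, right.orientation)
        if la:
            o_s, o_e, r_s, r_e = max(la, key=lambda t: t[1])
            left_end = r_e + (llen - o_e)
        else:
            left_end = left.ref_start + llen
        if ra:
            o_s, o_e, r_s, r_e = min(ra, key=lambda t: t[0])
            right_start = r_s - o_s
        else:
            right_start = right.ref_start
        size = right_start - left_end
        gaps.append(
            GapRecord(
                left_id=left.contig_id,
                right_id=right.contig_id,
                size=int(size),
                overlap=size < 0,
            )
        )
    return gaps
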