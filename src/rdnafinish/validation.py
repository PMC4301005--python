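"""Final-assembly acceptance: every original draft contig (including
previously masked rRNA contigs) must be represented in the finished sequence.

Placement is hierarchical. Contigs are first localized by unique-k-mer
anchors (cheap and exact for ordinary contigs); alignment then runs
against that local window only. Contigs without unique anchors — rRNA
isoform contigs match a dozen near-identical operons — are aligned against
the whole finished sequence, which is affordable at their size. Alignment
itself is recursive split-alignment: a segment is aligned whole
(edit-distance, infix mode, distance capped at the identity budget); on
failure it is bisected and each half retried, with a global-search fallback
so a segment whose true home lies outside the local window (a misassembled
block) still places. N bases encode absence of information and are excluded
from identity and coverage denominators; the finished sequence is virtually
doubled so contigs spanning the origin of a circular genome still place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .iupac import kmer_codes, revcomp
from .scaffold import ReferenceIndex
from .seqio import Contig

# N in the draft matches anything: unknown bases carry no evidence either way
_N_EQUALITIES = [("N", b) for b in "ACGT"]


@dataclass(frozen=True)
class ContigPlacement:
    contig_id: str
    identity: float  # percent over non-N bases of aligned segments
    covered_fraction: float  # fraction of non-N bases in passing segments
    start: int | None  # best segment location modulo genome length
    end: int | None
    strand: str | None
    informative_bases: int
    note: str = ""


@dataclass
class CoverageReport:
    placements: list[ContigPlacement]
    failing: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failing


_CHUNK = 15_000  # bp: contigs are verified in chunks of this size
_CHEAP_K = 300  # first-attempt edit band; nearly-exact segments succeed here
_FULL_BAND_CAP = 50_000  # bp: largest piece granted a full-budget band


def _try_align(seg: str, target: str, offset: int, max_div: float):
    """(edit distance, (start, end)) in full-target coordinates, or None.

    Alignment is banded: a cheap band is tried first and the full identity
    budget only on pieces small enough that the wide band stays affordable;
    larger divergent pieces are instead bisected by the caller until their
    halves qualify.
    """
    informative = len(seg) - seg.count("N")
    budget = int(informative * max_div) + 1
    bands = [budget] if budget <= _CHEAP_K else [_CHEAP_K]
    if budget > _CHEAP_K and (len(seg) <= _FULL_BAND_CAP or budget <= 600):
        bands.append(budget)
    for k in bands:
        res = edlib.align(seg, target, mode="HW", task="locations", k=k,
                          additionalEqualities=_N_EQUALITIES)
        if res["editDistance"] >= 0:
            s, e = res["locations"][0]
            return res["editDistance"], (offset + s, offset + e + 1)
    return None


_GLOBAL_SEARCH_CAP = 20_000  # bp: largest piece allowed a whole-genome search


def _place_recursive(seg, local, offset, target, idx, k, max_div, min_piece, out):
    """Append (piece length, informative, matched, location) tuples.

    On local failure the piece is re-anchored to its own window (a
    misassembled block lives far from its parent's window); pieces without
    anchors fall back to a whole-genome search once they are small enough
    for it to be affordable.
    """
    informative = len(seg) - seg.count("N")
    if informative == 0:
        out.append((len(seg), 0, 0, None))
        return
    res = _try_align(seg, local, offset, max_div)
    if res is None:
        own = _anchor_window(seg, idx, k)
        if own is not None:
            _, lo, hi = own
            pad = len(seg) + 2000
            w_lo, w_hi = max(0, lo - pad), min(len(target), hi + pad)
            if (w_lo, w_hi) != (offset, offset + len(local)):
                res = _try_align(seg, target[w_lo:w_hi], w_lo, max_div)
        elif len(seg) <= _GLOBAL_SEARCH_CAP:
            res = _try_align(seg, target, 0, max_div)
    if res is not None:
        dist, loc = res
        out.append((len(seg), informative, informative - dist, loc))
        return
    if len(seg) <= min_piece:
        out.append((len(seg), informative, 0, None))
        return
    mid = len(seg) // 2
    _place_recursive(seg[:mid], local, offset, target, idx, k, max_div, min_piece, out)
    _place_recursive(seg[mid:], local, offset, target, idx, k, max_div, min_piece, out)


def _anchor_window(
    seq: str, idx: ReferenceIndex, k: int
) -> tuple[str, int, int] | None:
    """(strand, ref_lo, ref_hi) from unique-k-mer matches, or None."""
    best = None
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        codes, starts = kmer_codes(s, k)
        qpos, rpos = idx.lookup(codes, starts)
        if len(qpos) < 5:
            continue
        lo, hi = np.percentile(rpos, [10, 90])
        cand = (len(qpos), strand, int(lo), int(hi))
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        return None
    _, strand, lo, hi = best
    return strand, lo, hi


def verify_draft_coverage(
    contigs: list[Contig],
    final_assembly: str | Contig,
    min_identity: float = 99.0,
    min_covered: float = 0.99,
    circular: bool = True,
    min_piece: int = 500,
    k: int = 21,
) -> CoverageReport:
    """Align every draft contig to the finished sequence and check that each
    meets the identity and coverage thresholds."""
    final = final_assembly.seq if isinstance(final_assembly, Contig) else final_assembly
    if not final:
        raise ValueError("final assembly must be non-empty")
    genome_len = len(final)
    target = final + final if circular else final
    idx = ReferenceIndex(final, k)
    max_div = 1.0 - min_identity / 100.0
    placements: list[ContigPlacement] = []
    failing: list[str] = []
    for c in contigs:
        informative_total = c.length - c.seq.count("N")
        if informative_total == 0:
            placements.append(
                ContigPlacement(c.id, 100.0, 1.0, None, None, None, 0,
                                note="no informative bases")
            )
            continue
        anchored = _anchor_window(c.seq, idx, k)
        strands = [anchored[0]] if anchored is not None else ["+", "-"]
        best_pieces, best_matched, best_strand = None, -1, None
        for strand in strands:
            seq = c.seq if strand == "+" else revcomp(c.seq)
            pieces: list = []
            for lo in range(0, len(seq), _CHUNK):
                chunk = seq[lo : lo + _CHUNK]
                own = _anchor_window(chunk, idx, k)
                if own is not None:
                    _, a_lo, a_hi = own
                    pad = len(chunk) + 2000
                    w_lo = max(0, a_lo - pad)
                    w_hi = min(len(target), a_hi + pad)
                    local, offset = target[w_lo:w_hi], w_lo
                else:
                    local, offset = target, 0
                _place_recursive(chunk, local, offset, target, idx, k, max_div,
                                 min_piece, pieces)
            matched = sum(m for _, _, m, _ in pieces)
            if matched > best_matched:
                best_pieces, best_matched, best_strand = pieces, matched, strand
        pieces = best_pieces
        informative_placed = sum(inf for _, inf, m, _ in pieces if m > 0 or inf == 0)
        denom = sum(inf for _, inf, _, _ in pieces)
        identity = 100.0 * best_matched / max(1, denom)
        covered = informative_placed / informative_total
        best = max((p for p in pieces if p[3] is not None), key=lambda p: p[2], default=None)
        start = end = None
        if best is not None:
            s, e = best[3]
            start, end = s % genome_len, ((e - 1) % genome_len) + 1
        ok = identity >= min_identity and covered >= min_covered
        placements.append(
            ContigPlacement(
                c.id, round(identity, 3), round(covered, 4), start, end,
                best_strand, informative_total, note="" if ok else "below threshold",
            )
        )
        if not ok:
            failing.append(c.id)
    return CoverageReport(placements=placements, failing=failing)
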