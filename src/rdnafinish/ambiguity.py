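"""Ambiguous-base (N-run) handling: detection, flanking primer design, and
placement of small contigs into N-stretches.

Assemblers emit runs of N between linked but unsequenced positions; their
lengths are in-silico estimates, not measurements. Each stretch is a short,
pre-defined gap: a primer pair reading across it defines the verification
amplicon, and a small contig whose ends reproduce the host sequence
flanking a stretch can be merged into it outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .iupac import revcomp
from .primers import (
    Primer,
    PrimerConstraints,
    Undesignable,
    UniquenessScope,
    design_primer,
)
from .seqio import Contig


@dataclass(frozen=True)
class NStretch:
    contig_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FlankingPrimerPair:
    stretch: NStretch
    forward: Primer
    reverse: Primer


@dataclass(frozen=True)
class PlacementMatch:
    small_id: str
    host_id: str
    stretch: NStretch
    orientation: str
    left_identity: float
    right_identity: float

    @property
    def score(self) -> float:
        return (self.left_identity + self.right_identity) / 2


@dataclass(frozen=True)
class UnplacedReport:
    small_id: str
    reason: str
    candidates: tuple[PlacementMatch, ...] = ()


def find_n_stretches(contig: Contig, min_length: int = 3) -> list[NStretch]:
    """Maximal runs of N of at least ``min_length`` bp, in coordinate order."""
    out: list[NStretch] = []
    seq = contig.seq
    i = seq.find("N")
    while i != -1:
        j = i
        while j < len(seq) and seq[j] == "N":
            j += 1
        if j - i >= min_length:
            out.append(NStretch(contig.id, i, j))
        i = seq.find("N", j)
    return out


def design_n_flanking_primers(
    contig: Contig,
    stretch: NStretch,
    constraints: PrimerConstraints = PrimerConstraints(),
    scope: UniquenessScope | None = None,
    search_window: int = 350,
) -> FlankingPrimerPair | Undesignable:
    """Primer pair reading across an N-stretch: forward upstream on '+',
    reverse downstream on '-', each within ``search_window`` bp of the
    stretch boundary."""
    up_lo = stretch.start - search_window
    if up_lo < 0 and stretch.start < constraints.min_len:
        return Undesignable("insufficient upstream flanking sequence")
    if len(contig.seq) - stretch.end < constraints.min_len:
        return Undesignable("insufficient downstream flanking sequence")
    fwd = design_primer(
        contig.seq,
        window=(max(0, up_lo), stretch.start),
        direction="+",
        constraints=constraints,
        scope=scope,
        name=f"{stretch.contig_id}_{stretch.start}F",
    )
    if isinstance(fwd, Undesignable):
        return Undesignable(f"forward: {fwd.reason}", fwd.failures)
    rev = design_primer(
        contig.seq,
        window=(stretch.end, min(len(contig.seq), stretch.end + search_window)),
        direction="-",
        constraints=constraints,
        scope=scope,
        name=f"{stretch.contig_id}_{stretch.start}R",
    )
    if isinstance(rev, Undesignable):
        return Undesignable(f"reverse: {rev.reason}", rev.failures)
    return FlankingPrimerPair(stretch=stretch, forward=fwd, reverse=rev)


def _flank_identity(a: str, b: str) -> float:
    """Identity of two flank-length sequences under edit alignment."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def place_small_contigs(
    small_contigs: list[Contig],
    hosts: list[Contig],
    stretches: list[NStretch],
    flank_window: int = 300,
    min_flank_identity: float = 0.95,
    length_tolerance: float = 0.5,
) -> tuple[list[PlacementMatch], list[UnplacedReport], list[Contig]]:
    """Fit small contigs into N-stretches whose host flanks they reproduce.

    A small contig is placed when both of its ends align to the host
    sequence flanking a stretch (both orientations tried) at or above
    ``min_flank_identity``; each contig is placed at most once (best mean
    flank identity wins, equal-best is ambiguous and reported unplaced).
    Accepted placements replace the flank+N+flank host segment with the
    small contig; the merged length may differ from the host length by up
    to ``length_tolerance`` of the stretch length (the N-run length is an
    estimate). Returns (placements, unplaced reports, updated host list
    with small contigs consumed).
    """
    host_by_id = {h.id: h for h in hosts}
    placements: list[PlacementMatch] = []
    unplaced: list[UnplacedReport] = []
    for small in small_contigs:
        if small.length < 2 * flank_window:
            unplaced.append(UnplacedReport(small.id, "shorter than two flank windows"))
            continue
        candidates: list[PlacementMatch] = []
        for st in stretches:
            host = host_by_id.get(st.contig_id)
            if host is None:
                continue
            if st.start < flank_window or host.length - st.end < flank_window:
                continue
            left = host.seq[st.start - flank_window : st.start]
            right = host.seq[st.end : st.end + flank_window]
            if "N" in left or "N" in right:
                continue
            insert_len = small.length - 2 * flank_window
            if abs(insert_len - st.length) > length_tolerance * st.length:
                continue
            for orient in "+-":
                seq = small.seq if orient == "+" else revcomp(small.seq)
                li = _flank_identity(left, seq[:flank_window])
                if li < min_flank_identity:
                    continue
                ri = _flank_identity(right, seq[-flank_window:])
                if ri < min_flank_identity:
                    continue
                candidates.append(
                    PlacementMatch(small.id, host.id, st, orient, round(li, 4), round(ri, 4))
                )
        if not candidates:
            unplaced.append(UnplacedReport(small.id, "no stretch with matching flanks"))
            continue
        candidates.sort(key=lambda m: -m.score)
        if len(candidates) > 1 and candidates[0].score == candidates[1].score and (
            candidates[0].stretch != candidates[1].stretch
        ):
            unplaced.append(
                UnplacedReport(small.id, "ambiguous: multiple equally good stretches",
                               tuple(candidates[:2]))
            )
            continue
        placements.append(candidates[0])

    # resolve stretch collisions: best score per stretch wins
    by_stretch: dict[tuple[str, int, int], PlacementMatch] = {}
    for m in sorted(placements, key=lambda m: -m.score):
        key = (m.stretch.contig_id, m.stretch.start, m.stretch.end)
        if key in by_stretch:
            unplaced.append(UnplacedReport(m.small_id, "stretch claimed by a better match"))
        else:
            by_stretch[key] = m
    placements = sorted(by_stretch.values(), key=lambda m: (m.host_id, m.stretch.start))

    # merge (right-to-left per host so earlier coordinates stay valid)
    small_by_id = {s.id: s for s in small_contigs}
    merged_seq = {h.id: h.seq for h in hosts}
    for m in sorted(placements, key=lambda m: (m.host_id, -m.stretch.start)):
        seq = small_by_id[m.small_id].seq
        if m.orientation == "-":
            seq = revcomp(seq)
        host_seq = merged_seq[m.host_id]
        merged_seq[m.host_id] = (
            host_seq[: m.stretch.start - flank_window]
            + seq
            + host_seq[m.stretch.end + flank_window :]
        )
    # unplaced small contigs remain in the working set
    placed_ids = {m.small_id for m in placements}
    updated = [Contig(h.id, merged_seq[h.id]) for h in hosts] + [
        s for s in small_contigs if s.id not in placed_ids
    ]
    return placements, unplaced, updated
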