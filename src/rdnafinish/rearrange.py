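"""Rearrangement detection by windowed draft-vs-reference placement.

The draft is cut into overlapping windows (10 kb, 5 kb step); each window is
placed at its best unique-k-mer-supported reference location. Windows are
then segmented into collinear runs (consistent strand and diagonal offset);
the extent-weighted monotone chain of runs is taken as the backbone, and
runs excluded from it become rearrangement calls: inversions when the
strand is flipped, relocations otherwise, annotated insertion-at-N when a
breakpoint abuts an ambiguous-base stretch (misassemblies are typically
stitched through exactly such stretches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .ambiguity import NStretch
from .iupac import kmer_codes, revcomp
from .primers import (
    Primer,
    PrimerConstraints,
    Undesignable,
    UniquenessScope,
    design_primer,
    simulate_pcr,
)
from .scaffold import ReferenceIndex


@dataclass(frozen=True)
class WindowPlacement:
    window_id: int
    d_start: int
    d_end: int
    r_start: int | None
    r_end: int | None
    strand: str | None
    support: float  # fraction of window k-mers agreeing with the placement

    @property
    def placed(self) -> bool:
        return self.r_start is not None


@dataclass(frozen=True)
class RearrangementCall:
    d_start: int
    d_end: int
    r_start: int
    r_end: int
    type: str  # relocation | inversion | insertion-at-N
    strand: str
    supporting_windows: tuple[int, ...]

    @property
    def block_size(self) -> int:
        return self.d_end - self.d_start


def window_map(
    draft: str,
    reference: str | ReferenceIndex,
    window: int = 10_000,
    step: int = 5_000,
    k: int = 21,
    min_support: int = 30,
) -> list[WindowPlacement]:
    """Place each draft window at its best unique-anchor reference location.

    A placement needs at least ``min_support`` reference-unique k-mer
    matches agreeing on one diagonal cluster (within one step); windows
    without such support are reported unplaced.
    """
    if isinstance(reference, str):
        if not reference:
            raise ValueError("reference must be non-empty")
        reference = ReferenceIndex(reference, k)
    idx = reference
    out: list[WindowPlacement] = []
    wid = 0
    pos = 0
    n = len(draft)
    while pos < n:
        w_end = min(n, pos + window)
        sub = draft[pos:w_end]
        best = None  # (count, strand, ref_start, ref_end, support_frac)
        for strand in "+-":
            q = sub if strand == "+" else revcomp(sub)
            codes, starts = kmer_codes(q, k)
            total = max(1, len(codes))
            qpos, rpos = idx.lookup(codes, starts)
            if len(qpos) < min_support:
                continue
            diag = rpos - qpos
            med = int(median(diag.tolist()))
            agree = np.abs(diag - med) <= step
            cnt = int(agree.sum())
            if cnt < min_support:
                continue
            r_lo = int(rpos[agree].min())
            r_hi = int(rpos[agree].max()) + k
            cand = (cnt, strand, r_lo, r_hi, cnt / total)
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            out.append(WindowPlacement(wid, pos, w_end, None, None, None, 0.0))
        else:
            _, strand, r_lo, r_hi, frac = best
            out.append(WindowPlacement(wid, pos, w_end, r_lo, r_hi, strand, round(frac, 4)))
        wid += 1
        if w_end == n:
            break
        pos += step
    return out


def _offset(p: WindowPlacement) -> int:
    # diagonal invariant: constant along a collinear run on either strand
    if p.strand == "+":
        return p.r_start - p.d_start
    return p.r_start + p.d_end


@dataclass
class _Run:
    windows: list[WindowPlacement] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.windows[0].strand

    @property
    def d_start(self) -> int:
        return self.windows[0].d_start

    @property
    def d_end(self) -> int:
        return self.windows[-1].d_end

    @property
    def extent(self) -> int:
        return self.d_end - self.d_start

    @property
    def r_start(self) -> int:
        return min(w.r_start for w in self.windows)

    @property
    def r_end(self) -> int:
        return max(w.r_end for w in self.windows)


def _segment_runs(placements: list[WindowPlacement], tol: int) -> list[_Run]:
    runs: list[_Run] = []
    for p in placements:
        if not p.placed:
            continue
        if (
            runs
            and runs[-1].strand == p.strand
            and abs(_offset(p) - _offset(runs[-1].windows[-1])) <= tol
        ):
            runs[-1].windows.append(p)
        else:
            runs.append(_Run(windows=[p]))
    return runs


def _backbone(runs: list[_Run], slack: int) -> set[int]:
    """Indices of the extent-weighted maximal monotone chain of runs.

    ``slack`` absorbs the ref-coordinate blur of boundary-straddling
    windows (up to about two window steps).
    """
    plus = sum(r.extent for r in runs if r.strand == "+")
    minus = sum(r.extent for r in runs if r.strand == "-")
    s_dom = "+" if plus >= minus else "-"
    cand = [i for i, r in enumerate(runs) if r.strand == s_dom]
    if not cand:
        return set()
    # weighted longest monotone subsequence over reference starts
    best_w = [0] * len(cand)
    prev = [-1] * len(cand)
    for a, i in enumerate(cand):
        best_w[a] = runs[i].extent
        for b in range(a):
            j = cand[b]
            mono = (
                runs[i].r_start >= runs[j].r_end - slack
                if s_dom == "+"
                else runs[i].r_end <= runs[j].r_start + slack
            )
            if mono and best_w[b] + runs[i].extent > best_w[a]:
                best_w[a] = best_w[b] + runs[i].extent
                prev[a] = b
    a = max(range(len(cand)), key=lambda x: best_w[x])
    chain = set()
    while a != -1:
        chain.add(cand[a])
        a = prev[a]
    return chain


def call_rearrangements(
    placements: list[WindowPlacement],
    min_jump: int = 50_000,
    step: int = 5_000,
    n_stretches: list[NStretch] | None = None,
) -> list[RearrangementCall]:
    """Merge discordantly-placed window runs into rearrangement calls.

    Runs outside the extent-weighted monotone backbone whose placement is at
    least ``min_jump`` away from (or strand-flipped against) their draft
    neighbors become calls.
    """
    runs = _segment_runs(placements, tol=2 * step)
    if len(runs) <= 1:
        return []
    backbone = _backbone(runs, slack=3 * step)
    calls: list[RearrangementCall] = []
    for i, run in enumerate(runs):
        if i in backbone:
            continue
        neighbors = [runs[j] for j in (i - 1, i + 1) if 0 <= j < len(runs)]
        discordant = False
        for nb in neighbors:
            if nb.strand != run.strand:
                discordant = True
            elif abs(_offset(run.windows[0]) - _offset(nb.windows[-1])) >= min_jump:
                discordant = True
        if not discordant:
            continue
        dominant_strand = "+" if sum(
            r.extent for r in runs if r.strand == "+"
        ) >= sum(r.extent for r in runs if r.strand == "-") else "-"
        ctype = "inversion" if run.strand != dominant_strand else "relocation"
        # draft boundaries via the diagonal: the run's reference extent is
        # tight (boundary-straddling windows only contribute k-mers from
        # their concordant side), while window extents overlap by a step
        offs = sorted(_offset(w) for w in run.windows)
        med_off = offs[len(offs) // 2]
        if run.strand == "+":
            d_start, d_end = run.r_start - med_off, run.r_end - med_off
        else:
            d_start, d_end = med_off - run.r_end, med_off - run.r_start
        d_start = max(d_start, run.d_start)
        d_end = min(d_end, run.d_end)
        if n_stretches is not None and ctype == "relocation":
            for st in n_stretches:
                if (
                    abs(st.end - d_start) <= 2 * step
                    or abs(st.start - d_end) <= 2 * step
                    or (d_start <= st.start and st.end <= d_end and (
                        st.start - d_start <= 2 * step or d_end - st.end <= 2 * step))
                ):
                    ctype = "insertion-at-N"
                    break
        calls.append(
            RearrangementCall(
                d_start=d_start,
                d_end=d_end,
                r_start=run.r_start,
                r_end=run.r_end,
                type=ctype,
                strand=run.strand,
                supporting_windows=tuple(w.window_id for w in run.windows),
            )
        )
    return calls


@dataclass(frozen=True)
class JunctionPrimerPair:
    junction: int  # draft coordinate of the hypothesized breakpoint
    left: Primer
    right: Primer
    product_length: int | None


def design_junction_primers(
    call: RearrangementCall,
    draft: str,
    constraints: PrimerConstraints = PrimerConstraints(),
    scope: UniquenessScope | None = None,
    reach: int = 1000,
) -> list[JunctionPrimerPair | Undesignable]:
    """One verification pair per hypothesized junction (block start and end):
    a primer on each side within ``reach`` bp of the breakpoint, with the
    expected in-silico product spanning the junction."""
    out: list[JunctionPrimerPair | Undesignable] = []
    for junction in (call.d_start, call.d_end):
        if junction < 100 or junction > len(draft) - 100:
            out.append(Undesignable(f"junction {junction}: too close to a sequence end"))
            continue
        left = design_primer(
            draft, window=(max(0, junction - reach), junction), direction="+",
            constraints=constraints, scope=scope, name=f"jx{junction}L",
        )
        if isinstance(left, Undesignable):
            out.append(Undesignable(f"junction {junction} left: {left.reason}", left.failures))
            continue
        right = design_primer(
            draft, window=(junction, min(len(draft), junction + reach)), direction="-",
            constraints=constraints, scope=scope, name=f"jx{junction}R",
        )
        if isinstance(right, Undesignable):
            out.append(Undesignable(f"junction {junction} right: {right.reason}", right.failures))
            continue
        lo = max(0, junction - reach - 100)
        hi = min(len(draft), junction + reach + 100)
        prods = simulate_pcr(draft[lo:hi], left, right, max_product=2 * reach + 200)
        spanning = next(
            (p for p in prods if lo + p.start <= junction <= lo + p.end), None
        )
        out.append(
            JunctionPrimerPair(
                junction=junction,
                left=left,
                right=right,
                product_length=spanning.length if spanning else None,
            )
        )
    return out
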