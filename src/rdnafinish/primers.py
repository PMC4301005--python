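"""Oligonucleotide model: Tm, GC, IUPAC-aware site search, in-silico PCR, and
constraint-driven primer design.

Hybridization semantics
-----------------------
A primer site is a template interval where the primer matches under IUPAC
expansion *on the primer side only* with at most ``max_mismatches``
mismatches and an exact match over the 3'-terminal run (3' mismatches block
polymerase extension in practice). Template Ns never match: an unknown base
cannot confirm hybridization. Sites are reported with the strand such that
extension proceeds 5'->3' into the template.

The melting temperature is nearest-neighbor (SantaLucia 2004 unified
parameters via Biopython) at 50 mM monovalent salt and 500 nM oligo;
degenerate primers are scored by their minimum-Tm disambiguation, a
conservative annealing estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

from .iupac import (
    IUPAC_SETS,
    primer_masks,
    revcomp,
    template_masks,
    validate_dna,
)

#: Universal 16S/23S primers (name -> (sequence 5'->3', gene, direction)).
#: 8F/1492R and 127F/2241R are the classic broadly conserved amplification
#: pairs; U1-U4 are operon-walking sequencing primers hybridizing near the
#: 5'/3' ends of the 16S and 23S genes.
UNIVERSAL_PRIMERS: dict[str, tuple[str, str, str]] = {
    "8F": ("AGAGTTTGATCCTGGCTCAG", "16S", "F"),
    "1492R": ("CGTTACCTTGTTACGACTT", "16S", "R"),
    "127F": ("CYGAATGGGRVAACC", "23S", "F"),
    "2241R": ("ACCGCCCCAGTHAAACT", "23S", "R"),
    "U1": ("TGGGATACCACCCTGATCGT", "16S", "R"),
    "U2": ("GTTTGGGCTAATCCGCGTTC", "16S", "F"),
    "U3": ("CCGTCACACCACGAGAGTTT", "23S", "R"),
    "U4": ("GTCCGCCGCTAGGTTGATTA", "23S", "F"),
}


@dataclass(frozen=True)
class TmConfig:
    """Nearest-neighbor Tm conditions (mM monovalent salt, nM oligo)."""

    na_mM: float = 50.0
    oligo_nM: float = 500.0
    max_expansions: int = 256


DEFAULT_TM = TmConfig()


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str

    def __post_init__(self) -> None:
        validate_dna(self.seq, where=f"primer {self.name!r}")
        if len(self.seq) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")

    @property
    def tm(self) -> float:
        return melting_temp(self.seq)

    @property
    def gc(self) -> float:
        return gc_content(self.seq)


@dataclass(frozen=True)
class PrimerSite:
    primer_name: str
    template_id: str
    start: int
    end: int
    strand: str  # '+' extends rightward, '-' leftward
    mismatches: int

    @property
    def three_prime(self) -> int:
        """Template coordinate just past the primer 3' end (the first
        extended base for '+', one past the last for '-')."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    fwd: PrimerSite
    rev: PrimerSite
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


def gc_content(seq: str) -> float:
    """GC percent; ambiguity codes contribute fractionally by the share of
    strong (G/C) bases among the bases they stand for (S counts fully)."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    validate_dna(seq, where="gc_content input")
    gc = 0.0
    for c in seq:
        s = IUPAC_SETS[c]
        gc += len(s & {"G", "C"}) / len(s)
    return 100.0 * gc / len(seq)


def _expansions(seq: str, cap: int):
    sets = [sorted(IUPAC_SETS[c]) for c in seq]
    n = 1
    for s in sets:
        n *= len(s)
        if n > cap:
            # too degenerate to enumerate: take the weakest (A) disambiguation
            return ["".join(s[0] if len(s) == 1 else "A" for s in sets)]
    return ["".join(p) for p in itertools.product(*sets)]


@lru_cache(maxsize=200_000)
def _tm_cached(seq: str, na: float, oligo: float, cap: int) -> float:
    vals = []
    for s in _expansions(seq, cap):
        vals.append(
            mt.Tm_NN(s, nn_table=mt.DNA_NN4, Na=na, dnac1=oligo, dnac2=0)
        )
    return min(vals)


def melting_temp(seq: str, config: TmConfig = DEFAULT_TM) -> float:
    """Nearest-neighbor Tm in deg C (minimum over IUPAC disambiguations)."""
    validate_dna(seq, where="melting_temp input")
    if len(seq) < 10:
        raise ValueError("melting_temp requires length >= 10")
    return _tm_cached(seq, config.na_mM, config.oligo_nM, config.max_expansions)


def wallace_tm(seq: str) -> float:
    """Rule-of-thumb 2(A+T)+4(G+C) Tm for short oligos (cross-check only)."""
    at = sum(seq.count(c) for c in "AT")
    gc = sum(seq.count(c) for c in "GC")
    return 2.0 * at + 4.0 * gc


def _scan_one(
    tmask: np.ndarray, primer_seq: str, max_mm: int, run3: int, three_prime_right: bool
) -> list[tuple[int, int]]:
    """Positions (start, mismatches) where primer_seq matches the template
    mask array; the 3'-terminal ``run3`` bases must match exactly on the side
    indicated by ``three_prime_right``."""
    pm = primer_masks(primer_seq)
    L = len(pm)
    n = len(tmask) - L + 1
    if n <= 0:
        return []
    mism = np.zeros(n, dtype=np.int16)
    tail = np.zeros(n, dtype=np.int16)
    for j in range(L):
        col = tmask[j : j + n]
        bad = (col & pm[j]) != col
        mism += bad
        in_tail = j >= L - run3 if three_prime_right else j < run3
        if in_tail:
            tail += bad
    hits = np.nonzero((mism <= max_mm) & (tail == 0))[0]
    return [(int(i), int(mism[i])) for i in hits]


def find_primer_sites(
    template: str | "object",
    primer: Primer | str,
    max_mismatches: int = 2,
    three_prime_run: int = 3,
    template_id: str = "template",
) -> list[PrimerSite]:
    """All hybridization sites of ``primer`` on both strands of ``template``.

    Accepts a raw sequence or a Contig-like object with .id/.seq.
    """
    if hasattr(template, "seq"):
        template_id = template.id
        template = template.seq
    if isinstance(primer, str):
        primer = Primer(name=primer, seq=primer)
    tmask = template_masks(template)
    L = len(primer.seq)
    sites = []
    for start, mm in _scan_one(tmask, primer.seq, max_mismatches, three_prime_run, True):
        sites.append(PrimerSite(primer.name, template_id, start, start + L, "+", mm))
    for start, mm in _scan_one(
        tmask, revcomp(primer.seq), max_mismatches, three_prime_run, False
    ):
        sites.append(PrimerSite(primer.name, template_id, start, start + L, "-", mm))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def simulate_pcr(
    template: str | "object",
    primer_a: Primer | str,
    primer_b: Primer | str,
    max_product: int = 15_000,
    max_mismatches: int = 2,
    three_prime_run: int = 3,
    template_id: str = "template",
) -> list[Amplicon]:
    """Predict PCR products: every convergent (+ site, - site) pair within
    the product-size cap, with either primer acting as forward."""
    if hasattr(template, "seq"):
        template_id = template.id
        template = template.seq
    if isinstance(primer_a, str):
        primer_a = Primer(name=primer_a, seq=primer_a)
    if isinstance(primer_b, str):
        primer_b = Primer(name=primer_b, seq=primer_b)
    sites: list[PrimerSite] = []
    for p in {primer_a.name: primer_a, primer_b.name: primer_b}.values():
        sites.extend(
            find_primer_sites(template, p, max_mismatches, three_prime_run, template_id)
        )
    fwd = [s for s in sites if s.strand == "+"]
    rev = [s for s in sites if s.strand == "-"]
    products: dict[tuple[int, int], Amplicon] = {}
    for f in fwd:
        for r in rev:
            if f.start >= r.start or f.end > r.end:
                continue
            length = r.end - f.start
            if length > max_product:
                continue
            key = (f.start, r.end)
            if key not in products:
                products[key] = Amplicon(
                    template_id, f.start, r.end, f, r, template[f.start : r.end]
                )
    return sorted(products.values(), key=lambda a: (a.length, a.start))


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 25
    tm_range: tuple[float, float] = (55.0, 65.0)
    gc_range: tuple[float, float] = (40.0, 60.0)
    max_mismatches: int = 2
    three_prime_run: int = 3


@dataclass(frozen=True)
class Undesignable:
    """Design failure report with per-constraint rejection counts."""

    reason: str
    failures: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return False


class UniquenessScope:
    """The sequence set a designed primer must hit exactly once.

    Holds precomputed template masks so repeated uniqueness checks across
    many designs share the encoding work.
    """

    def __init__(self, contigs) -> None:
        self.entries = []
        for c in contigs:
            seq = c.seq if hasattr(c, "seq") else c
            cid = c.id if hasattr(c, "id") else f"seq{len(self.entries)}"
            self.entries.append((cid, seq, template_masks(seq)))
        # concatenated text (+ revcomp) for a fast exact-substring prefilter
        joined = "#".join(e[1] for e in self.entries)
        self._text = joined + "#" + revcomp(joined)

    def exact_count(self, seq: str) -> int:
        return self._text.count(seq)

    def site_count(self, primer: Primer, constraints: PrimerConstraints, cap: int = 2) -> int:
        n = 0
        for cid, seq, tmask in self.entries:
            L = len(primer.seq)
            for right in (True, False):
                pseq = primer.seq if right else revcomp(primer.seq)
                n += len(
                    _scan_one(
                        tmask, pseq, constraints.max_mismatches,
                        constraints.three_prime_run, right,
                    )
                )
                if n > cap:
                    return n
        return n


def design_primer(
    template: str,
    window: tuple[int, int],
    direction: str,
    constraints: PrimerConstraints = PrimerConstraints(),
    scope: UniquenessScope | None = None,
    name: str = "primer",
    five_prime_range: tuple[int, int] | None = None,
) -> Primer | Undesignable:
    """Best constraint-satisfying primer whose footprint lies in
    ``window`` on ``template``, reading in ``direction``.

    For '+' the primer is the template substring (5' base = footprint
    start); for '-' it is the reverse complement (5' base = footprint
    end - 1). ``five_prime_range`` optionally restricts the 5'-base
    coordinate. Score: -|Tm - 60|, ties by smaller |GC - 50|, then leftmost.
    Returns Undesignable with per-constraint failure counts when no oligo
    qualifies.
    """
    if direction not in "+-":
        raise ValueError("direction must be '+' or '-'")
    a, b = max(0, window[0]), min(len(template), window[1])
    fails = {"window": 0, "n_bases": 0, "gc": 0, "tm": 0, "uniqueness": 0}
    if b - a < constraints.min_len:
        return Undesignable("search window shorter than minimum primer length", fails)

    # length 20 first (the workhorse oligo size), then the rest
    lengths = [20] + [
        L for L in range(constraints.min_len, constraints.max_len + 1) if L != 20
    ]
    best: tuple[tuple[float, float, int], Primer] | None = None
    for L in lengths:
        candidates = []
        for start in range(a, b - L + 1):
            five = start if direction == "+" else start + L - 1
            if five_prime_range is not None and not (
                five_prime_range[0] <= five < five_prime_range[1]
            ):
                fails["window"] += 1
                continue
            sub = template[start : start + L]
            if "N" in sub:
                fails["n_bases"] += 1
                continue
            pseq = sub if direction == "+" else revcomp(sub)
            gc = gc_content(pseq)
            if not constraints.gc_range[0] <= gc <= constraints.gc_range[1]:
                fails["gc"] += 1
                continue
            tm = melting_temp(pseq)
            if not constraints.tm_range[0] <= tm <= constraints.tm_range[1]:
                fails["tm"] += 1
                continue
            candidates.append((abs(tm - 60.0), abs(gc - 50.0), start, pseq))
        for score in sorted(candidates):
            dtm, dgc, start, pseq = score
            primer = Primer(name=name, seq=pseq)
            if scope is not None:
                if scope.exact_count(pseq) > 1:
                    fails["uniqueness"] += 1
                    continue
                if scope.site_count(primer, constraints, cap=1) != 1:
                    fails["uniqueness"] += 1
                    continue
            key = (dtm, dgc, start)
            if best is None or key < best[0]:
                best = (key, primer)
            break  # candidates are sorted: first acceptable is best for this length
        if best is not None:
            return best[1]
    reason = "no constraint-satisfying primer in window"
    if fails["uniqueness"]:
        reason = "no unique primer in window (repeat-rich flank?)"
    return Undesignable(reason, fails)


def purity_check(
    template: str,
    distant_pairs: list[tuple[Primer | str, Primer | str]],
    max_product: int = 15_000,
) -> dict:
    """Template-purity analog of control PCRs with primer pairs targeting
    distant genomic loci: pass when none of them amplifies from the
    candidate template."""
    offenders = []
    for i, (p1, p2) in enumerate(distant_pairs):
        prods = simulate_pcr(template, p1, p2, max_product=max_product)
        if prods:
            offenders.append({"pair_index": i, "product_lengths": [p.length for p in prods]})
    return {"pass": not offenders, "offending_pairs": offenders}
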