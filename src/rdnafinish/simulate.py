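"""Synthetic genomes and corrupted draft assemblies with full ground truth.

The generator emulates the structure of a ~6 Mb *Paenibacillus*-like
chromosome: ~45% GC background, a dozen near-identical (but not identical)
rDNA operons with variable intragenic spacers, and the documented
short-read draft-assembly failure modes layered on top — whole operons
falling into inter-contig gaps, rRNA gene fragments at contig boundaries,
short chimeric rRNA-isoform contigs, ambiguous-base (N) stretches of
estimated length, small contigs that belong inside N-stretches, and one
large segmental relocation stitched through an N-stretch.

Operon copies are synthesized de novo around fixed universal-primer
footprints (8F/1492R, 127F/2241R, U1-U4) which are kept mutation-free, so
universal primers always find their sites; everything else diverges
between copies at the configured rate. All randomness flows from one seed
and regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .iupac import revcomp
from .primers import UNIVERSAL_PRIMERS
from .rdna import ConsensusGene
from .seqio import Contig

#: strain-CR1 gap-specific primer pairs (contig-gap name -> (forward, reverse)),
#: used for junction verification and template-purity controls
CR1_GAP_PRIMERS: dict[str, tuple[str, str]] = {
    "5-1": ("AATAGACGGGTCTTCCTGCTTATAC", "CGATACAACAGCCGACATTTGATTA"),
    "5-6": ("ACCCTAATCGACTGCTTAATCTTGT", "CATCTATTGAACTCATTGAACGGGG"),
    "6-10": ("GATGAACCAAAACCTCACCAAGAAT", "CGATTGGATCAAGATATTCGCTACG"),
    "10-3": ("GCATCCACAATACGACCCATAAAAT", "GAATGTAGGACGAACGGGTAAAATC"),
    "3-4": ("CGGATTACCTCAAAAGGATTGGATG", "AAAGAACCATCATGCACAGACAAAT"),
    "12-1": ("GTGCCGTTCTAATGTGTAGCTTATC", "AGATGGATAGTAGTCAGGCAAATCC"),
    "9-2": ("GTATATCGGGGAAAGAGTAGGCAAT", "GGTGTTTGTGTTGTAAGCTGTATGA"),
    "8-4": ("TTGTTTGATACGTTTGGTACCTTGG", "TCTCCAAGTCAGCGTTCGTC"),
    "13-11": ("GACATGGTTGATTGAAAGTGACTGG", "AGTGCTCAGCATGGAAGCAA"),
    "11-7": ("TGGTCAATGTAAAACGCAATCTTCA", "CCATCATATCCGGGCACCAA"),
    "7-15": ("GCACTGAATAATCCCATTCTCAACC", "TGAGGCAACAAGAATCCGCT"),
    "4-15": ("ACATGTTGCTTTCTTTTGCTGA", "GGACAACCAGGATACCGCAA"),
    "4-13": ("AACCTGCTGATTATGCGGCT", "AGTGCTTGCAAAGTTGGCTC"),
}

_GENE_LEN = {"16S": 1550, "23S": 2900, "5S": 116}
_ITS_RANGE = (400, 600)
_SPACER = 60

# concrete disambiguations used when planting degenerate-primer footprints
_127F_CONCRETE = "CTGAATGGGAGAACC"  # Y->T, R->A, V->G
_2241R_CONCRETE = "ACCGCCCCAGTAAAACT"  # H->A


def _plant(seq: bytearray, pos: int, text: str) -> list[int]:
    seq[pos : pos + len(text)] = text.encode()
    return list(range(pos, pos + len(text)))


@dataclass(frozen=True)
class OperonTruth:
    start: int
    end: int
    strand: str
    genes: dict  # gene name -> (start, end) in genome coordinates


@dataclass
class GenomeTruth:
    seq: str
    operons: list[OperonTruth]
    gc: float
    seed: int
    master_genes: dict  # gene name -> master sequence
    planted_amplicons: dict = field(default_factory=dict)  # name -> (start, end)

    def consensus_genes(self) -> list[ConsensusGene]:
        return [ConsensusGene(n, s) for n, s in self.master_genes.items()]


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> bytearray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(rng.choice(bases, size=n, p=p).tobytes())


def _build_master_genes(rng: np.random.Generator, gc: float):
    """Master subunit genes with universal-primer footprints planted at
    their canonical positions; returns (genes, protected positions)."""
    genes: dict[str, str] = {}
    protected: dict[str, set[int]] = {}
    g16 = _random_dna(rng, _GENE_LEN["16S"], gc + 0.05)
    prot = set()
    prot.update(_plant(g16, 0, UNIVERSAL_PRIMERS["8F"][0]))
    prot.update(_plant(g16, 60, revcomp(UNIVERSAL_PRIMERS["U1"][0])))
    prot.update(_plant(g16, 1420, UNIVERSAL_PRIMERS["U2"][0]))
    prot.update(_plant(g16, _GENE_LEN["16S"] - 19, revcomp(UNIVERSAL_PRIMERS["1492R"][0])))
    genes["16S"], protected["16S"] = g16.decode(), prot
    g23 = _random_dna(rng, _GENE_LEN["23S"], gc + 0.05)
    prot = set()
    prot.update(_plant(g23, 112, _127F_CONCRETE))
    prot.update(_plant(g23, 150, revcomp(UNIVERSAL_PRIMERS["U3"][0])))
    prot.update(_plant(g23, 2820, UNIVERSAL_PRIMERS["U4"][0]))
    prot.update(_plant(g23, 2241 - len(_2241R_CONCRETE), revcomp(_2241R_CONCRETE)))
    genes["23S"], protected["23S"] = g23.decode(), prot
    g5 = _random_dna(rng, _GENE_LEN["5S"], gc + 0.05)
    genes["5S"], protected["5S"] = g5.decode(), set()
    return genes, protected


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, protected: set[int] | None = None
) -> str:
    if rate <= 0:
        return seq
    arr = bytearray(seq.encode())
    n_mut = rng.binomial(len(arr), rate)
    if n_mut == 0:
        return seq
    positions = rng.choice(len(arr), size=n_mut, replace=False)
    others = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
    for p in positions:
        if protected and int(p) in protected:
            continue
        cur = arr[p]
        if cur in others:
            arr[p] = others[cur][rng.integers(0, 3)]
    return arr.decode()


def generate_genome(
    size: int = 6_000_000,
    operon_count: int = 12,
    divergence: float = 0.02,
    gc: float = 0.45,
    seed: int = 42,
    planted_amplicons: dict[str, tuple[str, str, int]] | None = None,
    margin: int = 60_000,
) -> GenomeTruth:
    """Background i.i.d. sequence at the given GC hosting ``operon_count``
    copies of one master operon, each with independent substitutions at the
    divergence rate and intragenic-spacer length jitter.

    ``planted_amplicons`` optionally plants named primer-pair footprints
    (forward, reverse, product length) at operon-free loci.
    """
    rng = np.random.default_rng(seed)
    master, protected = _build_master_genes(rng, gc)
    max_operon = _GENE_LEN["16S"] + _ITS_RANGE[1] + _GENE_LEN["23S"] + _SPACER + _GENE_LEN["5S"]
    if size < operon_count * (max_operon + 2 * margin):
        raise ValueError("genome too small to host the requested operons with spacing")
    genome = _random_dna(rng, size, gc)
    master_its = _random_dna(rng, _ITS_RANGE[1], gc).decode()
    master_spacer = _random_dna(rng, _SPACER, gc).decode()

    # evenly sectored operon anchor positions with jitter
    sector = size // operon_count
    positions = sorted(
        int(i * sector + margin + rng.integers(0, max(1, sector - max_operon - 2 * margin)))
        for i in range(operon_count)
    )
    operons: list[OperonTruth] = []
    for pos in positions:
        # zero divergence means literally identical copies: no spacer jitter
        its_len = (
            int(rng.integers(*_ITS_RANGE)) if divergence > 0
            else (_ITS_RANGE[0] + _ITS_RANGE[1]) // 2
        )
        its = _mutate(rng, master_its[:its_len], divergence)
        g16 = _mutate(rng, master["16S"], divergence, protected["16S"])
        g23 = _mutate(rng, master["23S"], divergence, protected["23S"])
        g5 = _mutate(rng, master["5S"], divergence, protected["5S"])
        spacer = _mutate(rng, master_spacer, divergence)
        operon = g16 + its + g23 + spacer + g5
        genome[pos : pos + len(operon)] = operon.encode()
        s16 = pos
        s23 = pos + len(g16) + its_len
        s5 = s23 + len(g23) + _SPACER
        operons.append(
            OperonTruth(
                start=pos,
                end=pos + len(operon),
                strand="+",
                genes={
                    "16S": (s16, s16 + len(g16)),
                    "ITS": (s16 + len(g16), s23),
                    "23S": (s23, s23 + len(g23)),
                    "5S": (s5, s5 + len(g5)),
                },
            )
        )

    amp_truth: dict[str, tuple[int, int]] = {}
    if planted_amplicons:
        # drop each into the widest operon-free stretch midpoints
        free_anchor = positions[0] - margin // 2
        offset = 0
        for name, (fwd, rev, plen) in planted_amplicons.items():
            filler_len = plen - len(fwd) - len(rev)
            if filler_len < 0:
                raise ValueError(f"planted amplicon {name}: product shorter than primers")
            start = free_anchor + offset
            cassette = fwd + _random_dna(rng, filler_len, gc).decode() + revcomp(rev)
            genome[start : start + plen] = cassette.encode()
            amp_truth[name] = (start, start + plen)
            offset += plen + 2000
    return GenomeTruth(
        seq=genome.decode(),
        operons=operons,
        gc=gc,
        seed=seed,
        master_genes=master,
        planted_amplicons=amp_truth,
    )


# ---------------------------------------------------------------------------
# draft corruption
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DraftProfile:
    contig_count: int = 38
    rrna_only_count: int = 10
    n_run_count: int = 198
    n_run_range: tuple[int, int] = (9, 769)
    placeable_count: int = 10
    relocation_bp: int = 200_000
    non_rdna_gap_range: tuple[int, int] = (10_000, 14_000)
    gene_cut_in: int = 200  # bp of gene left on contig ends flanking rDNA gaps
    flip_probability: float = 0.3
    isoform_divergence: float = 0.003

    @property
    def main_count(self) -> int:
        return self.contig_count - self.rrna_only_count - self.placeable_count


CR1_LIKE = DraftProfile()


@dataclass(frozen=True)
class StretchTruth:
    contig: str
    start: int  # draft contig coordinates (final orientation)
    end: int
    true_seq: str
    placeable: bool
    small_contig: str | None = None


@dataclass(frozen=True)
class GapTruth:
    left: str  # contig name
    right: str
    true_seq: str
    rdna: bool
    operon_index: int | None


@dataclass(frozen=True)
class RelocationTruth:
    src_start: int  # original genome coordinates
    src_end: int
    dest_start: int  # relocated genome coordinates
    dest_end: int


@dataclass
class DraftTruth:
    contigs: list[Contig]
    order: list[tuple[str, str]]  # (contig name, orientation) in genome order
    gaps: list[GapTruth]
    stretches: list[StretchTruth]
    rrna_only: list[str]
    small_contigs: list[str]
    relocation: RelocationTruth | None
    relocated_genome: str
    seed: int

    def contig(self, name: str) -> Contig:
        return next(c for c in self.contigs if c.id == name)


def _operon_free_intervals(
    size: int, operons: list[OperonTruth], forbidden: list[tuple[int, int]], pad: int
) -> list[tuple[int, int]]:
    blocks = sorted(
        [(o.start - pad, o.end + pad) for o in operons]
        + [(s - pad, e + pad) for s, e in forbidden]
    )
    free = []
    pos = 0
    for s, e in blocks:
        if s > pos:
            free.append((pos, s))
        pos = max(pos, e)
    if pos < size:
        free.append((pos, size))
    return free


def corrupt_to_draft(
    truth: GenomeTruth,
    profile: DraftProfile = CR1_LIKE,
    seed: int = 42,
) -> DraftTruth:
    """Break a genome into a draft assembly exhibiting the documented
    short-read failure modes; see the module docstring. The returned truth
    inverts every operator (see :func:`reconstruct_genome`)."""
    rng = np.random.default_rng(seed)
    genome = truth.seq
    size = len(genome)
    n_operons = len(truth.operons)
    if profile.main_count < 2:
        raise ValueError("profile leaves fewer than two main contigs")
    n_gaps = profile.main_count - 1
    n_rdna_gaps = min(n_operons, n_gaps)
    n_free_gaps = n_gaps - n_rdna_gaps

    forbidden = list(truth.planted_amplicons.values())

    # --- 1. segmental relocation -------------------------------------------
    relocation = None
    if profile.relocation_bp:
        B = profile.relocation_bp
        free = [
            iv for iv in _operon_free_intervals(size, truth.operons, forbidden, 25_000)
            if iv[1] - iv[0] > B + 50_000
        ]
        if len(free) < 2:
            raise ValueError("no room for the requested relocation block")
        src_iv = free[0]
        a = src_iv[0] + 20_000
        dest_iv = free[-1]
        d = dest_iv[0] + (dest_iv[1] - dest_iv[0]) // 2
        if d < a + B:
            raise ValueError("relocation source/destination overlap")
        genome = genome[:a] + genome[a + B : d] + genome[a : a + B] + genome[d:]
        relocation = RelocationTruth(a, a + B, d - B, d)

        def remap(p: int) -> int:
            if p < a:
                return p
            if p < a + B:
                return d - B + (p - a)
            if p < d:
                return p - B
            return p

    else:

        def remap(p: int) -> int:
            return p

    operons = [
        OperonTruth(
            start=remap(o.start),
            end=remap(o.end),
            strand=o.strand,
            genes={g: (remap(s), remap(e)) for g, (s, e) in o.genes.items()},
        )
        for o in truth.operons
    ]
    forbidden = [(remap(s), remap(e)) for s, e in forbidden]

    # --- 2. gap intervals ---------------------------------------------------
    cut = profile.gene_cut_in
    gap_ivs: list[tuple[int, int, int | None]] = []  # (start, end, operon index)
    for i, o in enumerate(operons[:n_rdna_gaps]):
        gap_ivs.append((o.genes["16S"][0] + cut, o.end - cut, i))
    reserved = [(s, e) for s, e, _ in gap_ivs] + forbidden
    if relocation:
        reserved.append((relocation.dest_start - 30_000, relocation.dest_end + 30_000))
    for _ in range(n_free_gaps):
        glen = int(rng.integers(*profile.non_rdna_gap_range))
        for _try in range(200):
            p = int(rng.integers(60_000, size - 60_000 - glen))
            if all(p + glen + 20_000 < s or p > e + 20_000 for s, e in reserved):
                gap_ivs.append((p, p + glen, None))
                reserved.append((p, p + glen))
                break
        else:
            raise ValueError("could not place a non-rDNA gap")
    gap_ivs.sort()

    # --- 3. cut into main segments -----------------------------------------
    segments: list[str] = []
    gap_records: list[tuple[str, int | None]] = []
    pos = 0
    for s, e, op_i in gap_ivs:
        segments.append(genome[pos:s])
        gap_records.append((genome[s:e], op_i))
        pos = e
    segments.append(genome[pos:])
    assert len(segments) == profile.main_count

    # --- 4. N-runs and placeable excisions ---------------------------------
    total_len = sum(len(s) for s in segments)
    runs_per_seg = [round(profile.n_run_count * len(s) / total_len) for s in segments]
    while sum(runs_per_seg) != profile.n_run_count:
        i = int(np.argmax([len(s) for s in segments]))
        runs_per_seg[i] += 1 if sum(runs_per_seg) < profile.n_run_count else -1

    # deliberate N-stretch adjacent to the relocation destination junction
    reloc_n_seg = None
    if relocation:
        seg_starts = []
        acc = 0
        for s, e, _ in gap_ivs:
            seg_starts.append(acc)
            acc = e
        seg_starts.append(acc)
        for si, seg in enumerate(segments):
            if seg_starts[si] <= relocation.dest_start < seg_starts[si] + len(seg):
                local = relocation.dest_start - seg_starts[si]
                if local > 1400:
                    reloc_n_seg = (si, local)
                break

    # the junction stretch consumes one of the segment's random slots
    free_runs = list(runs_per_seg)
    if reloc_n_seg:
        free_runs[reloc_n_seg[0]] -= 1
    slots = [(si, j) for si, n in enumerate(free_runs) for j in range(n)]
    chosen = rng.choice(len(slots), size=profile.placeable_count, replace=False)
    placeable_idx = {slots[int(i)] for i in chosen}

    margin = 800
    stretch_raw: list[tuple[int, list]] = []  # per segment: list of edits
    small_contigs: list[Contig] = []
    small_meta: list[tuple[str, int, int]] = []  # (name, segment idx, slot)
    n_small = 0
    for si, seg in enumerate(segments):
        n_runs = free_runs[si]
        edits = []  # (pos_in_original_segment, kind, n_len, excise_len)
        forbidden_local: list[tuple[int, int]] = []
        if reloc_n_seg and reloc_n_seg[0] == si:
            # one run ending just before the destination junction
            p = reloc_n_seg[1] - 520
            L = 500
            edits.append((p, "plain", L, L))
            forbidden_local.append((p - margin, p + L + margin))
        attempts = 0
        j = 0
        while j < n_runs and attempts < 5000:
            attempts += 1
            placeable = (si, j) in placeable_idx
            if placeable:
                excise = int(rng.integers(100, 401))
                n_len = int(np.clip(round(excise * rng.uniform(0.8, 1.2)), 9, 769))
            else:
                n_len = int(rng.integers(*profile.n_run_range))
                excise = n_len
            p = int(rng.integers(600, len(seg) - 600 - excise))
            span = (p - margin, p + excise + margin)
            if any(not (span[1] < s or span[0] > e) for s, e in forbidden_local):
                continue
            edits.append((p, "placeable" if placeable else "plain", n_len, excise))
            forbidden_local.append(span)
            j += 1
        if j < n_runs:
            raise ValueError("could not place all N-runs (profile too dense)")
        edits.sort()
        stretch_raw.append((si, edits))

    # apply edits left-to-right, tracking offsets, and emit small contigs
    seg_stretches: list[list[tuple[int, int, str, bool, str | None]]] = []
    new_segments: list[str] = []
    for si, edits in stretch_raw:
        seg = segments[si]
        parts = []
        recs = []
        prev = 0
        offset = 0
        for p, kind, n_len, excise in edits:
            parts.append(seg[prev:p])
            true_seq = seg[p : p + excise]
            small_name = None
            if kind == "placeable":
                n_small += 1
                small_name = f"small_{n_small}"
                piece = seg[p - 300 : p + excise + 300]
                if rng.random() < 0.5:
                    piece = revcomp(piece)
                small_contigs.append(Contig(small_name, piece))
            parts.append("N" * n_len)
            start = p + offset
            recs.append((start, start + n_len, true_seq, kind == "placeable", small_name))
            offset += n_len - excise
            prev = p + excise
        parts.append(seg[prev:])
        new_segments.append("".join(parts))
        seg_stretches.append(recs)

    # --- 5. rRNA-isoform contigs -------------------------------------------
    rrna_contigs: list[Contig] = []
    for i in range(profile.rrna_only_count):
        o = operons[i % len(operons)]
        gene = "16S" if i % 2 == 0 else "23S"
        gs, ge = o.genes[gene]
        max_len = min(ge - gs, 1900)
        L = int(rng.integers(1000, max_len + 1)) if max_len > 1000 else max_len
        off = int(rng.integers(0, ge - gs - L + 1))
        piece = _mutate(rng, genome[gs + off : gs + off + L], profile.isoform_divergence)
        rrna_contigs.append(Contig(f"rrna_iso_{i + 1}", piece))

    # --- 6. orientation flips, shuffling, renaming -------------------------
    orientations = ["-" if rng.random() < profile.flip_probability else "+" for _ in new_segments]
    final_main: list[tuple[str, list]] = []
    for si, seq in enumerate(new_segments):
        recs = seg_stretches[si]
        if orientations[si] == "-":
            L = len(seq)
            seq = revcomp(seq)
            recs = [
                (L - e, L - s, revcomp(ts), pl, sm)
                for (s, e, ts, pl, sm) in sorted(recs)
            ]
            recs.sort()
        final_main.append((seq, recs))

    all_entries: list[tuple[str, str]] = []  # (uid, seq)
    for si, (seq, _recs) in enumerate(final_main):
        all_entries.append((f"main_{si}", seq))
    for c in rrna_contigs:
        all_entries.append((c.id, c.seq))
    for c in small_contigs:
        all_entries.append((c.id, c.seq))
    order_idx = sorted(range(len(all_entries)), key=lambda i: (-len(all_entries[i][1]), i))
    width = len(str(len(all_entries)))
    names = {}
    for rank, i in enumerate(order_idx, start=1):
        names[all_entries[i][0]] = f"contig_{rank:0{width}d}"

    contigs = [Contig(names[uid], seq) for uid, seq in all_entries]
    order = [(names[f"main_{si}"], orientations[si]) for si in range(len(new_segments))]
    stretches = [
        StretchTruth(names[f"main_{si}"], s, e, ts, pl, names[sm] if sm else None)
        for si, (_seq, recs) in enumerate(final_main)
        for (s, e, ts, pl, sm) in recs
    ]
    gaps = [
        GapTruth(
            left=names[f"main_{i}"],
            right=names[f"main_{i + 1}"],
            true_seq=gseq,
            rdna=op_i is not None,
            operon_index=op_i,
        )
        for i, (gseq, op_i) in enumerate(gap_records)
    ]
    return DraftTruth(
        contigs=contigs,
        order=order,
        gaps=gaps,
        stretches=stretches,
        rrna_only=[names[c.id] for c in rrna_contigs],
        small_contigs=[names[c.id] for c in small_contigs],
        relocation=relocation,
        relocated_genome=genome,
        seed=seed,
    )


def reconstruct_genome(truth: GenomeTruth, draft: DraftTruth) -> str:
    """Invert every corruption operator using the recorded truth: reorder
    and reorient the main contigs, restore N-stretches, refill gaps, and
    undo the relocation. The result must equal the source genome exactly."""
    by_name = {c.id: c for c in draft.contigs}
    st_by_contig: dict[str, list[StretchTruth]] = {}
    for st in draft.stretches:
        st_by_contig.setdefault(st.contig, []).append(st)
    pieces = []
    for i, (name, orientation) in enumerate(draft.order):
        seq = by_name[name].seq
        for st in sorted(st_by_contig.get(name, []), key=lambda s: -s.start):
            seq = seq[: st.start] + st.true_seq + seq[st.end :]
        if orientation == "-":
            seq = revcomp(seq)
        pieces.append(seq)
        if i < len(draft.gaps):
            pieces.append(draft.gaps[i].true_seq)
    relocated = "".join(pieces)
    if draft.relocation is None:
        return relocated
    r = draft.relocation
    block = relocated[r.dest_start : r.dest_end]
    without = relocated[: r.dest_start] + relocated[r.dest_end :]
    return without[: r.src_start] + block + without[r.src_start :]


def cr1_like_fixture(seed: int = 42, size: int = 6_000_000):
    """The full study-condition preset: 6 Mb genome, 12 divergent operons,
    38 draft contigs (10 rRNA-only, 10 placeable small), 198 N-runs of
    9-769 bp, one 200 kb relocation, and the CR1 "4-13" junction primer
    footprints planted with a sub-1-kb product."""
    fwd, rev = CR1_GAP_PRIMERS["4-13"]
    truth = generate_genome(
        size=size,
        operon_count=12,
        divergence=0.02,
        gc=0.45,
        seed=seed,
        planted_amplicons={"4-13": (fwd, rev, 900)},
    )
    draft = corrupt_to_draft(truth, CR1_LIKE, seed=seed)
    return truth, draft
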