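"""Sequence I/O: FASTA/FASTQ/GenBank readers, FASTA writer, core record types.

Coordinates are 0-based half-open everywhere; GenBank's 1-based inclusive
feature locations are converted on ingestion (Biopython already does this).
Sequences are upper-cased and U (RNA) is folded to T; anything outside the
IUPAC nucleotide alphabet is a fatal parse error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .iupac import IUPAC_ALPHABET, validate_dna


@dataclass(frozen=True)
class Contig:
    """A draft sequence unit over the IUPAC alphabet (N allowed)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        validate_dna(self.seq, where=f"contig {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QualityRecord:
    """Per-base Phred scores for one read; Q = -10*log10(e)."""

    id: str
    quals: tuple[int, ...]


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a reference (0-based half-open)."""

    type: str
    start: int
    end: int
    strand: str  # '+' or '-'


def _clean(raw: str, where: str) -> str:
    seq = raw.upper().replace("U", "T")
    validate_dna(seq, where=where)
    return seq


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a multi-record FASTA into Contigs, order preserved.

    Duplicate ids, empty sequences, and non-IUPAC characters are fatal.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        seq = _clean(str(rec.seq), where=f"record {rec.id!r}")
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, seq=seq))
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


def read_fastq_quals(path: str | Path) -> list[QualityRecord]:
    """Read Sanger Phred+33 FASTQ quality strings."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(QualityRecord(id=rec.id, quals=tuple(rec.letter_annotations["phred_quality"])))
    if not out:
        raise ValueError(f"no FASTQ records found in {path}")
    return out


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("LOCUS"):
                return "genbank"
            break
    raise ValueError(f"unrecognized reference format in {path} (expected FASTA or GenBank)")


def parse_reference(path: str | Path) -> tuple[Contig, list[Feature]]:
    """Read a finished reference from FASTA or a GenBank flat file.

    Returns the (first) sequence plus rRNA/tRNA/CDS features with 0-based
    half-open coordinates; FASTA input yields an empty feature list.
    """
    path = Path(path)
    fmt = _sniff_format(path)
    rec = next(SeqIO.parse(str(path), fmt))
    seq = _clean(str(rec.seq), where=f"reference {rec.id!r}")
    features: list[Feature] = []
    if fmt == "genbank":
        for f in rec.features:
            if f.type not in ("rRNA", "tRNA", "CDS"):
                continue
            strand = "-" if f.location.strand == -1 else "+"
            features.append(
                Feature(type=f.type, start=int(f.location.start), end=int(f.location.end), strand=strand)
            )
    return Contig(id=rec.id, seq=seq), features
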