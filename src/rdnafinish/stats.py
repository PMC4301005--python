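"""Assembly and sequencing-run QC statistics: N50, Q30 fraction, coverage."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import Contig, QualityRecord


@dataclass(frozen=True)
class AssemblyStats:
    contig_count: int
    total_bases: int
    n50: int
    coverage: float | None = None


def n50(contigs: Sequence[Contig] | Sequence[int]) -> int:
    """Contig size at which, combined with all longer contigs, half of the
    total assembly bases are accounted for."""
    lengths = sorted(
        (c.length if isinstance(c, Contig) else int(c) for c in contigs), reverse=True
    )
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    half = sum(lengths) / 2
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def q30_fraction(records: Iterable[QualityRecord], threshold: int = 30) -> float:
    """Fraction of bases at or above the Phred threshold (Q = -10*log10(e))."""
    total = 0
    good = 0
    for rec in records:
        total += len(rec.quals)
        good += sum(1 for q in rec.quals if q >= threshold)
    if total == 0:
        raise ValueError("q30_fraction needs at least one base")
    return good / total


def estimate_coverage(total_read_bases: int, genome_size: int) -> float:
    """Sequencing depth (fold) = total read bases / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if total_read_bases < 0:
        raise ValueError("total read bases must be non-negative")
    return total_read_bases / genome_size


def assembly_stats(
    contigs: Sequence[Contig], total_read_bases: int | None = None
) -> AssemblyStats:
    total = sum(c.length for c in contigs)
    cov = estimate_coverage(total_read_bases, total) if total_read_bases else None
    return AssemblyStats(
        contig_count=len(contigs), total_bases=total, n50=n50(contigs), coverage=cov
    )
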