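"""IUPAC nucleotide alphabet: sets, complements, bitmasks, and fast k-mer encoding.

The bitmask convention (A=1, C=2, G=4, T=8) lets ambiguity codes be unions of
base bits; a template N is encoded as a disjoint bit (16) so that it never
satisfies a primer match (an unknown template base cannot confirm
hybridization), while a primer N (mask 15) matches any concrete base.
"""

from __future__ import annotations

import numpy as np

# code -> set of concrete bases it stands for
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# set of bases -> code (for consensus tie-breaking)
SETS_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(_COMP)

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}


def code_mask(code: str) -> int:
    """Bitmask of the concrete bases an IUPAC code can stand for."""
    return sum(_BASE_BIT[b] for b in IUPAC_SETS[code])


def complement(seq: str) -> str:
    return seq.translate(_COMP_TABLE)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


# --- numpy byte-level tables ---------------------------------------------

# template masks: concrete bases + ambiguity codes as base unions, except N -> 16
_TEMPLATE_MASK = np.zeros(256, dtype=np.uint8)
for _c in IUPAC_SETS:
    _TEMPLATE_MASK[ord(_c)] = code_mask(_c)
_TEMPLATE_MASK[ord("N")] = 16

# primer masks: plain IUPAC unions (N matches anything)
_PRIMER_MASK = np.zeros(256, dtype=np.uint8)
for _c in IUPAC_SETS:
    _PRIMER_MASK[ord(_c)] = code_mask(_c)

# 2-bit codes for k-mer packing; 255 marks non-ACGT
_TWOBIT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _TWOBIT[ord(_c)] = _i


def template_masks(seq: str) -> np.ndarray:
    """Per-base hybridization masks for a template sequence (N never matches)."""
    return _TEMPLATE_MASK[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def primer_masks(seq: str) -> np.ndarray:
    """Per-base masks for a primer sequence (IUPAC expanded, N matches all)."""
    return _PRIMER_MASK[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def twobit(seq: str) -> np.ndarray:
    """Sequence as 0..3 codes, 255 for any non-ACGT character."""
    return _TWOBIT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer of ``seq`` into a uint64 (2 bits/base, 5' base most
    significant).

    Returns (codes, starts); k-mers containing non-ACGT characters are
    dropped. k must be <= 31.
    """
    if not 0 < k <= 31:
        raise ValueError("k must be in 1..31")
    b = twobit(seq)
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = b[j : j + n]
        valid &= col != 255
        codes = (codes << np.uint64(2)) | col.astype(np.uint64)
    starts = np.nonzero(valid)[0]
    return codes[starts], starts


def validate_dna(seq: str, where: str = "sequence") -> None:
    """Raise ValueError naming the offending character on non-IUPAC input."""
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ValueError(
            f"{where}: non-IUPAC character(s) {sorted(bad)!r}"
        )
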