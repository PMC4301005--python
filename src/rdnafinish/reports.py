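"""Artifact writers: TSV, BED, JSON, and the primer-table format.

Machine outputs (JSON, BED) use 0-based half-open coordinates; human TSV
reports carry 1-based inclusive columns suffixed ``_1based``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from .primers import Primer


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    return str(obj)


def write_json(path: str | Path, obj: Any) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1)
        fh.write("\n")


def write_tsv(path: str | Path, rows: Iterable[dict], columns: list[str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(list(rows))
    if columns:
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False)


def write_bed(path: str | Path, intervals: Iterable[tuple]) -> None:
    """6-column BED: (chrom, start, end, name, score, strand)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_primer_tsv(path: str | Path, primers: Iterable[tuple[Primer, str, str]]) -> None:
    """Primer table with (name, sequence, gene, direction) columns."""
    rows = [
        {"name": p.name, "sequence": p.seq, "gene": gene, "direction": direction}
        for p, gene, direction in primers
    ]
    write_tsv(path, rows, columns=["name", "sequence", "gene", "direction"])


def read_primer_tsv(path: str | Path) -> list[tuple[Primer, str, str]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            (Primer(str(row["name"]), str(row["sequence"])),
             str(row.get("gene", "")), str(row.get("direction", "")))
        )
    return out
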