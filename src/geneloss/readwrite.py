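"""Readers and writers for the plain-text formats used across the pipeline.

FASTA handling is deliberately strict: empty records and sequence data
before the first header are parse errors that name the offending line,
because silently dropped records are a classic source of missing taxa in
downstream alignments.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping


class ParseError(ValueError):
    """Malformed input file (message names file and line where known)."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are upper-cased; IUPAC ambiguity codes and gap characters are
    preserved as-is. Record order follows the file.
    """
    path = Path(path)
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        if current is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{lineno}: empty record '{current}'")
        records[current] = seq

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if name in records:
                    raise ParseError(f"{path}:{lineno}: duplicate id '{name}'")
                current = name
                chunks = []
            else:
                if current is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line.upper())
        if current is None:
            raise ParseError(f"{path}: no FASTA records found")
        _flush(lineno + 1)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences in input order, wrapping lines at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    """Read a headered TSV into a list of row dicts (empty cells -> '')."""
    with open(path, newline="") as fh:
        return [dict(row) for row in csv.DictReader(fh, delimiter="\t")]


def write_tsv(rows: Iterable[Mapping[str, object]], path: str | Path,
              columns: list[str] | None = None) -> None:
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})
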