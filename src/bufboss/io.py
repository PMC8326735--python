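"""FASTA/FASTQ ingestion (multi-line FASTA, quality ignored, gzip accepted)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

from Bio import SeqIO


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle) -> str:
    pos = handle.tell()
    first = ""
    for line in handle:
        if line.strip():
            first = line.lstrip()[0]
            break
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError("file is neither FASTA nor FASTQ")


def read_records(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from a FASTA/FASTQ file, plain or gzipped."""
    with _open_text(path) as handle:
        fmt = _sniff_format(handle)
        for rec in SeqIO.parse(handle, fmt):
            yield rec.id, str(rec.seq)


def read_sequences(path) -> list[str]:
    """All sequences of a FASTA/FASTQ file as upper-case strings."""
    return [seq.upper() for _, seq in read_records(path)]
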