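"""Lightweight sequence-file reading shared by the CLI and drivers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

from Bio import SeqIO


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, uppercase sequence) from FASTA or FASTQ."""
    path = Path(path)
    fmt = "fastq" if path.suffix in (".fastq", ".fq") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper()
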