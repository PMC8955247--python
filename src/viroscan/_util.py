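"""Shared low-level helpers: sequence ops and FASTA/TSV plumbing."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly-gzipped text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs; id is the first whitespace token."""
    header: str | None = None
    chunks: list[str] = []
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:].split()[0]
                chunks = []
            else:
                if header is None:
                    raise ValueError("FASTA sequence before first header")
                chunks.append(line.strip().upper())
        if header is not None:
            yield header, "".join(chunks)


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
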