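"""Per-virus small-RNA profiles from mapped unique reads.

A profile holds, for one virus in one library: the unique-read mapping
percentage, a length-by-strand histogram over 18-32 nt, the 5' nucleotide
composition per (length, strand) cell, per-strand coverage vectors, and a
coverage-uniformity measure.

Conventions: percentages use unique (collapsed) reads in both numerator and
denominator; the 5' base of a minus-strand read is the first base of the
read as sequenced (reverse-complement orientation); T is reported as U.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .srnamap import MappedRead, SmallRead

LEN_MIN, LEN_MAX = 18, 32
BASES = ("U", "A", "C", "G")


class ProfileIntegrityError(ValueError):
    pass


@dataclass
class VsRNAProfile:
    virus_abbrev: str
    sample_id: str
    n_unique_mapped: int
    n_unique_library: int
    pct_unique_mapped: float
    raw_mapped: int
    length_hist: dict[tuple[int, str], int]
    first_base_comp: dict[tuple[int, str], dict[str, int]]
    coverage_plus: np.ndarray
    coverage_minus: np.ndarray
    uniformity: float  # breadth: fraction of positions with depth >= 1
    coverage_cv: float = 0.0  # coefficient of variation of total depth

    @property
    def genome_length(self) -> int:
        return len(self.coverage_plus)

    def strand_counts(self) -> tuple[int, int]:
        plus = sum(c for (_, s), c in self.length_hist.items() if s == "+")
        minus = sum(c for (_, s), c in self.length_hist.items() if s == "-")
        return plus, minus


def collapse_reads(reads: Sequence[SmallRead | str]) -> list[tuple[str, int]]:
    """Deduplicate identical sequences; returns (sequence, copy_count)
    sorted by sequence for determinism. Copy counts sum to the input size."""
    counter: Counter[str] = Counter()
    for r in reads:
        counter[r if isinstance(r, str) else r.sequence] += 1
    return sorted(counter.items())


def profile_virus(
    mapped: Sequence[MappedRead],
    genome_length: int,
    n_unique_library: int,
    virus_abbrev: str | None = None,
    sample_id: str = "",
) -> VsRNAProfile:
    """Build the profile for one virus from its mapped unique reads."""
    viruses = {m.virus_abbrev for m in mapped}
    if len(viruses) > 1:
        raise ProfileIntegrityError(f"mapped reads span multiple viruses: {sorted(viruses)}")
    if virus_abbrev is None:
        virus_abbrev = next(iter(viruses)) if viruses else ""
    if n_unique_library < len(mapped):
        raise ProfileIntegrityError(
            f"library unique count {n_unique_library} < mapped unique count {len(mapped)}"
        )

    length_hist: dict[tuple[int, str], int] = defaultdict(int)
    first_base: dict[tuple[int, str], dict[str, int]] = defaultdict(
        lambda: {b: 0 for b in BASES}
    )
    cov_plus = np.zeros(genome_length, dtype=np.int64)
    cov_minus = np.zeros(genome_length, dtype=np.int64)
    raw_mapped = 0
    for m in mapped:
        L = len(m.read_sequence)
        if m.position + L > genome_length:
            raise ProfileIntegrityError(
                f"mapping at {m.position}+{L} exceeds genome length {genome_length}"
            )
        key = (L, m.strand)
        length_hist[key] += 1
        base = m.read_sequence[0].replace("T", "U")
        if base in first_base[key]:
            first_base[key][base] += 1
        raw_mapped += m.copy_count
        cov = cov_plus if m.strand == "+" else cov_minus
        cov[m.position : m.position + L] += 1

    total = cov_plus + cov_minus
    breadth = float((total > 0).mean()) if genome_length else 0.0
    mean = float(total.mean()) if genome_length else 0.0
    cv = float(total.std() / mean) if mean > 0 else 0.0
    n_mapped = len(mapped)
    pct = 100.0 * n_mapped / n_unique_library if n_unique_library else 0.0
    return VsRNAProfile(
        virus_abbrev=virus_abbrev,
        sample_id=sample_id,
        n_unique_mapped=n_mapped,
        n_unique_library=n_unique_library,
        pct_unique_mapped=pct,
        raw_mapped=raw_mapped,
        length_hist=dict(length_hist),
        first_base_comp={k: dict(v) for k, v in first_base.items()},
        coverage_plus=cov_plus,
        coverage_minus=cov_minus,
        uniformity=breadth,
        coverage_cv=cv,
    )


# ---------------------------------------------------------------------------
# tabular output

def write_profile_summary(profiles: Sequence[VsRNAProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "virus",
                "sample",
                "n_unique_mapped",
                "n_unique_library",
                "pct_unique_mapped",
                "raw_mapped",
                "breadth",
                "coverage_cv",
            ]
        )
        for p in profiles:
            w.writerow(
                [
                    p.virus_abbrev,
                    p.sample_id,
                    p.n_unique_mapped,
                    p.n_unique_library,
                    f"{p.pct_unique_mapped:.4f}",
                    p.raw_mapped,
                    f"{p.uniformity:.4f}",
                    f"{p.coverage_cv:.4f}",
                ]
            )


def write_histogram(profile: VsRNAProfile, path: str | Path) -> None:
    """Length/strand/5'-base histogram TSV (Fig-4-style stacked bars)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["virus", "length", "strand", "first_base", "count"])
        for length in range(LEN_MIN, LEN_MAX + 1):
            for strand in "+-":
                comp = profile.first_base_comp.get((length, strand), {})
                for base in BASES:
                    count = comp.get(base, 0)
                    if count:
                        w.writerow([profile.virus_abbrev, length, strand, base, count])


def write_coverage(profile: VsRNAProfile, path: str | Path) -> None:
    """Per-position depth TSV (virus, pos 1-based, strand, depth); zero-depth
    positions are omitted."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["virus", "pos", "strand", "depth"])
        for strand, cov in (("+", profile.coverage_plus), ("-", profile.coverage_minus)):
            for pos in np.nonzero(cov)[0]:
                w.writerow([profile.virus_abbrev, int(pos) + 1, strand, int(cov[pos])])
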