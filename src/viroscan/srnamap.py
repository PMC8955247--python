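"""Small-RNA read cleaning and exact/near-exact matching to viral genomes.

Cleaning keeps 18-32 nt reads and drops reads whose low-quality base
fraction exceeds a cutoff, plus empty and low-complexity sequences
(adapter trimming is assumed done upstream).

Matching uses a seed index over the genome set: seeds of ``seed_length`` nt
anchor candidate offsets, which are then verified by direct string
comparison on both strands. With max_mismatch <= 1 the two seeds at the
query ends cover every admissible alignment (pigeonhole), so the index is
exhaustive for 18-32 nt queries.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import open_text, revcomp


class FastqParseError(ValueError):
    pass


class DuplicateGenomeError(ValueError):
    pass


@dataclass(frozen=True)
class SmallRead:
    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MappedRead:
    """One unique read sequence placed on one viral genome. ``position`` is
    the 0-based start on the forward genome strand; strand '-' means the
    read matches the reverse complement. ``read_sequence`` is the read as
    sequenced."""

    read_sequence: str
    virus_abbrev: str
    position: int
    strand: str  # '+' or '-'
    mismatches: int
    copy_count: int = 1


@dataclass
class CleanStats:
    n_input: int = 0
    n_retained: int = 0
    removed_empty: int = 0
    removed_length: int = 0
    removed_quality: int = 0
    removed_low_complexity: int = 0


@dataclass
class MapStats:
    n_unique_input: int = 0
    n_unique_mapped_any: int = 0
    n_unique_unmapped: int = 0
    unique_mapped_per_virus: dict[str, int] = field(default_factory=dict)


def parse_fastq(path: str | Path) -> Iterable[SmallRead]:
    """Stream SmallReads from a (possibly gzipped) FASTQ file; parse errors
    name the failing record index."""
    with open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ near record {index}: {exc}") from exc
            index += 1
            yield SmallRead(
                id=title.split()[0],
                sequence=seq.upper(),
                qualities=tuple(ord(c) - 33 for c in qual),
            )


def _homopolymer_fraction(seq: str) -> float:
    if not seq:
        return 1.0
    return max(seq.count(b) for b in "ACGTN") / len(seq)


def clean_reads(
    raw: Iterable[SmallRead] | str | Path,
    min_len: int = 18,
    max_len: int = 32,
    max_lowqual_frac: float = 0.20,
    qual_threshold: int = 20,
    max_homopolymer_frac: float = 0.8,
) -> tuple[list[SmallRead], CleanStats]:
    """Apply the length window, low-quality-fraction rule and low-complexity
    rule. Each removed read is tallied under the first failing rule."""
    if isinstance(raw, (str, Path)):
        raw = parse_fastq(raw)
    stats = CleanStats()
    kept: list[SmallRead] = []
    for read in raw:
        stats.n_input += 1
        if read.length == 0:
            stats.removed_empty += 1
            continue
        if not (min_len <= read.length <= max_len):
            stats.removed_length += 1
            continue
        if read.qualities is not None and read.qualities:
            low = sum(1 for q in read.qualities if q < qual_threshold)
            if low / len(read.qualities) > max_lowqual_frac:
                stats.removed_quality += 1
                continue
        if _homopolymer_fraction(read.sequence) > max_homopolymer_frac:
            stats.removed_low_complexity += 1
            continue
        kept.append(read)
        stats.n_retained += 1
    return kept, stats


class MatchIndex:
    """Seed-and-verify matcher over a set of genomes, supporting exact and
    one-mismatch lookup of 18-32 nt queries on both strands."""

    def __init__(self, genomes: Sequence[tuple[str, str]], seed_length: int = 9):
        if seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        names = [g[0] for g in genomes]
        if len(set(names)) != len(names):
            raise DuplicateGenomeError("duplicate genome abbreviation")
        self.seed_length = seed_length
        self.genomes: dict[str, str] = {}
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in genomes:
            seq = seq.upper()
            if not seq:
                raise ValueError(f"genome {name!r} is empty")
            self.genomes[name] = seq
            for i in range(len(seq) - seed_length + 1):
                self._seeds[seq[i : i + seed_length]].append((name, i))

    def _candidates(self, query: str) -> set[tuple[str, int]]:
        """Candidate (genome, offset) anchors from the two end seeds."""
        k = self.seed_length
        L = len(query)
        out: set[tuple[str, int]] = set()
        for qoff in (0, L - k):
            for name, pos in self._seeds.get(query[qoff : qoff + k], ()):
                start = pos - qoff
                if start >= 0 and start + L <= len(self.genomes[name]):
                    out.add((name, start))
        return out

    @staticmethod
    def _mismatches(a: str, b: str, limit: int) -> int:
        if a == b:
            return 0
        mm = 0
        for x, y in zip(a, b):
            if x != y:
                mm += 1
                if mm > limit:
                    return mm
        return mm

    def lookup(self, query: str, max_mismatch: int = 0) -> list[tuple[str, int, str, int]]:
        """All placements of ``query`` with <= max_mismatch substitutions:
        list of (virus, position, strand, mismatches). Queries containing N
        never match. Exhaustive for max_mismatch <= 1 when
        2*seed_length <= len(query)."""
        if max_mismatch > 1:
            raise ValueError("max_mismatch must be 0 or 1")
        query = query.upper()
        if "N" in query:
            return []
        hits: list[tuple[str, int, str, int]] = []
        rc = revcomp(query)
        exhaustive = max_mismatch == 1 and len(query) < 2 * self.seed_length
        for strand, q in (("+", query), ("-", rc)):
            if exhaustive:
                candidates = {
                    (name, start)
                    for name, seq in self.genomes.items()
                    for start in range(len(seq) - len(q) + 1)
                }
            else:
                candidates = self._candidates(q)
            for name, start in candidates:
                window = self.genomes[name][start : start + len(q)]
                mm = self._mismatches(q, window, max_mismatch)
                if mm <= max_mismatch:
                    hits.append((name, start, strand, mm))
        hits.sort(key=lambda h: (h[0], h[3], h[1], h[2]))
        return hits


def build_index(genomes: Sequence[tuple[str, str]], seed_length: int = 9) -> MatchIndex:
    return MatchIndex(genomes, seed_length=seed_length)


def map_reads(
    reads: Sequence[SmallRead],
    index: MatchIndex,
    max_mismatch: int = 0,
) -> tuple[list[MappedRead], MapStats]:
    """Collapse reads to unique sequences and place each on every genome it
    matches. Within one virus a multi-mapping sequence is reported once at
    its leftmost best placement; across viruses it is counted once per
    virus (profiles are per-virus independent)."""
    from .profile import collapse_reads

    collapsed = collapse_reads(reads)
    stats = MapStats(n_unique_input=len(collapsed))
    per_virus: dict[str, int] = defaultdict(int)
    mapped: list[MappedRead] = []
    for seq, count in collapsed:
        hits = index.lookup(seq, max_mismatch=max_mismatch)
        if not hits:
            stats.n_unique_unmapped += 1
            continue
        stats.n_unique_mapped_any += 1
        best_by_virus: dict[str, tuple[str, int, str, int]] = {}
        for hit in hits:  # hits sorted by (virus, mismatches, position, strand)
            best_by_virus.setdefault(hit[0], hit)
        for virus, (_, pos, strand, mm) in sorted(best_by_virus.items()):
            per_virus[virus] += 1
            mapped.append(
                MappedRead(
                    read_sequence=seq,
                    virus_abbrev=virus,
                    position=pos,
                    strand=strand,
                    mismatches=mm,
                    copy_count=count,
                )
            )
    stats.unique_mapped_per_virus = dict(per_virus)
    return mapped, stats


def write_mappings(mapped: Sequence[MappedRead], path: str | Path) -> None:
    """Mappings TSV; positions are 1-based in file output."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence", "virus", "pos_1based", "strand", "mismatches", "copy_count"])
        for m in mapped:
            w.writerow(
                [m.read_sequence, m.virus_abbrev, m.position + 1, m.strand, m.mismatches, m.copy_count]
            )


def write_sam(
    mapped: Sequence[MappedRead], genomes: Sequence[tuple[str, str]], path: str | Path
) -> None:
    """Minimal SAM export for inspection in genome browsers."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genomes:
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for i, m in enumerate(mapped):
            flag = 16 if m.strand == "-" else 0
            seq = revcomp(m.read_sequence) if m.strand == "-" else m.read_sequence
            fh.write(
                f"read{i}\t{flag}\t{m.virus_abbrev}\t{m.position + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{m.mismatches}\n"
            )
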