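"""Viral-candidate triage over assembled contigs.

Filters, applied conjunctively in a fixed order:

1. viral_hit  — at least one homology hit against the viral database with
   e-value <= viral_evalue_max (default 1e-5);
2. length     — contig length >= min_length (default 2000 nt);
3. host       — NO homology hit against the host genome with e-value <=
   host_evalue_max (default 1e-100);
4. orf        — at least one open reading frame of >= min_orf_aa codons.

A separate terminal-coverage confirmation checks read depth at both genome
ends against the global mean.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import read_fasta, revcomp

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

FILTER_ORDER = ("viral_hit", "length", "host", "orf", "terminal_coverage")

#: discard reason associated with each filter, in evaluation order
REASON_FOR_FILTER = {
    "viral_hit": "no_viral_hit",
    "length": "too_short",
    "host": "host_genome",
    "orf": "no_orf",
    "terminal_coverage": "low_terminal_coverage",
}


class ReferentialError(ValueError):
    """A hit table references a contig id absent from the contig set."""


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular homology-search output."""

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatch: int
    gapopen: int
    aln_start: int  # 1-based inclusive, on the query
    aln_end: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue} for {self.query_id}")


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame in forward-strand coordinates (0-based,
    half-open). ``aa_length`` excludes the stop codon when one is present."""

    contig_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    start: int
    end: int
    aa_length: int
    has_stop: bool


@dataclass
class ContigVerdict:
    contig_id: str
    kept: bool
    reasons: list[str] = field(default_factory=list)
    passed_filters: list[str] = field(default_factory=list)
    length: int = 0
    best_viral_evalue: float | None = None
    best_host_evalue: float | None = None


@dataclass(frozen=True)
class TriageParams:
    viral_evalue_max: float = 1e-5
    min_length: int = 2000
    host_evalue_max: float = 1e-100
    min_orf_aa: int = 25
    require_start: bool = False


def _scan_frame(seq: str, offset: int, min_aa_length: int, require_start: bool):
    """Yield (start, end, aa_length, has_stop) for maximal ORFs in one
    forward frame of ``seq``. Codons containing N are non-coding and break
    the frame without being part of any ORF."""
    n = len(seq)
    seg_start = offset
    i = offset
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if "N" in codon:
            yield from _emit(seq, seg_start, i, False, min_aa_length, require_start)
            seg_start = i + 3
        elif codon in STOP_CODONS:
            yield from _emit(seq, seg_start, i + 3, True, min_aa_length, require_start)
            seg_start = i + 3
        i += 3
    yield from _emit(seq, seg_start, i, False, min_aa_length, require_start)


def _emit(seq, seg_start, seg_end, has_stop, min_aa_length, require_start):
    """Trim a stop-free codon segment to the ORF policy and yield it if long
    enough. seg_end includes the terminating stop codon when has_stop."""
    if require_start:
        i = seg_start
        limit = seg_end - 3 if has_stop else seg_end
        while i + 3 <= limit:
            if seq[i : i + 3] == START_CODON:
                seg_start = i
                break
            i += 3
        else:
            return
    n_codons = (seg_end - seg_start) // 3
    aa = n_codons - 1 if has_stop else n_codons
    if aa >= min_aa_length:
        yield seg_start, seg_end, aa, has_stop


def find_orfs(
    contig: Contig, min_aa_length: int = 25, require_start: bool = False
) -> list[OrfCall]:
    """Six-frame ORF scan; maximal stop-free runs on both strands, reported
    in forward-strand coordinates and sorted by aa_length descending."""
    if not contig.sequence:
        raise ValueError(f"contig {contig.id}: empty sequence")
    if min_aa_length < 1:
        raise ValueError("min_aa_length must be >= 1")
    seq = contig.sequence.upper()
    L = len(seq)
    calls: list[OrfCall] = []
    for offset in range(3):
        for s, e, aa, stop in _scan_frame(seq, offset, min_aa_length, require_start):
            calls.append(OrfCall(contig.id, offset + 1, s, e, aa, stop))
    rc = revcomp(seq)
    for offset in range(3):
        for s, e, aa, stop in _scan_frame(rc, offset, min_aa_length, require_start):
            calls.append(OrfCall(contig.id, -(offset + 1), L - e, L - s, aa, stop))
    calls.sort(key=lambda c: (-c.aa_length, c.start, c.frame))
    return calls


def triage_contigs(
    contigs: Sequence[Contig],
    viral_hits: Sequence[HomologyHit],
    host_hits: Sequence[HomologyHit],
    params: TriageParams | None = None,
) -> list[ContigVerdict]:
    """Apply the four-filter cascade; a discarded contig carries every
    applicable reason, in filter order."""
    params = params or TriageParams()
    known = {c.id for c in contigs}
    for hit in list(viral_hits) + list(host_hits):
        if hit.query_id not in known:
            raise ReferentialError(f"hit references unknown contig id {hit.query_id!r}")

    best_viral: dict[str, float] = {}
    for h in viral_hits:
        if h.query_id not in best_viral or h.evalue < best_viral[h.query_id]:
            best_viral[h.query_id] = h.evalue
    best_host: dict[str, float] = {}
    for h in host_hits:
        if h.query_id not in best_host or h.evalue < best_host[h.query_id]:
            best_host[h.query_id] = h.evalue

    verdicts = []
    for contig in contigs:
        v = ContigVerdict(contig_id=contig.id, kept=True, length=contig.length)
        v.best_viral_evalue = best_viral.get(contig.id)
        v.best_host_evalue = best_host.get(contig.id)
        checks = {
            "viral_hit": v.best_viral_evalue is not None
            and v.best_viral_evalue <= params.viral_evalue_max,
            "length": contig.length >= params.min_length,
            "host": not (
                v.best_host_evalue is not None
                and v.best_host_evalue <= params.host_evalue_max
            ),
            "orf": bool(
                find_orfs(contig, params.min_orf_aa, params.require_start)
            ),
        }
        for name in FILTER_ORDER[:4]:
            if checks[name]:
                v.passed_filters.append(name)
            else:
                v.reasons.append(REASON_FOR_FILTER[name])
        v.kept = not v.reasons
        verdicts.append(v)
    return verdicts


def terminal_coverage_check(
    depth: Sequence[int] | np.ndarray, end_window: int = 50, min_ratio: float = 0.2
) -> tuple[bool, dict]:
    """True iff mean depth in BOTH terminal windows is >= min_ratio times
    the global mean depth. Returns (decision, diagnostics)."""
    depth = np.asarray(depth, dtype=float)
    if len(depth) < 2 * end_window:
        raise ValueError(
            f"depth vector of length {len(depth)} shorter than 2 x end_window={end_window}"
        )
    global_mean = float(depth.mean())
    five = float(depth[:end_window].mean())
    three = float(depth[-end_window:].mean())
    diag = {
        "global_mean": global_mean,
        "mean_5prime": five,
        "mean_3prime": three,
        "end_window": end_window,
        "min_ratio": min_ratio,
    }
    if global_mean == 0.0:
        diag["zero_coverage"] = True
        return False, diag
    ok = five >= min_ratio * global_mean and three >= min_ratio * global_mean
    return ok, diag


# ---------------------------------------------------------------------------
# tabular I/O

def read_contigs_fasta(path: str | Path) -> list[Contig]:
    contigs = [Contig(name, seq) for name, seq in read_fasta(path)]
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in FASTA")
    return contigs


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column tabular homology output (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pident=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    aln_start=int(fields[6]),
                    aln_end=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def write_verdicts(verdicts: Sequence[ContigVerdict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["contig_id", "kept", "reasons", "length", "best_viral_evalue", "best_host_evalue"]
        )
        for v in verdicts:
            w.writerow(
                [
                    v.contig_id,
                    str(v.kept).lower(),
                    ",".join(v.reasons),
                    v.length,
                    "" if v.best_viral_evalue is None else f"{v.best_viral_evalue:.3g}",
                    "" if v.best_host_evalue is None else f"{v.best_host_evalue:.3g}",
                ]
            )
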