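"""Synthetic data with serialized ground truth for every pipeline stage:
genomes, class-labelled small-RNA libraries, qPCR measurements, and contig
sets with planted keep/discard verdicts.

All randomness flows through numpy Generators seeded explicitly; nothing
touches global random state, so fixed seeds give identical outputs across
runs and platforms.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import revcomp
from .abundance import QpcrMeasurement, StandardCurve
from .srnamap import SmallRead
from .triage import Contig, HomologyHit

BASES = "ACGT"

#: repeating this motif yields a stop codon within every 4 codons in all six
#: frames, so pure-repeat sequences carry no ORF of any practical length
NO_ORF_MOTIF = "AACT"

DEFAULT_SIRNA_LEN = {20: 0.15, 21: 0.70, 22: 0.15}
DEFAULT_PIRNA_LEN = {26: 0.30, 27: 0.40, 28: 0.30}
DEFAULT_DEGRADATION_LEN = {L: 1.0 / 15 for L in range(18, 33)}

FASTQ_QUALITY_CHAR = "?"  # constant Q30
LOW_QUALITY_CHAR = "#"  # Q2


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random genome of given length and GC content; deterministic per seed."""
    if length < 100:
        raise ValueError(f"genome length must be >= 100, got {length}")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list(BASES), size=length, p=probs))


@dataclass(frozen=True)
class SrnaLibrarySpec:
    """Recipe for a small-RNA library over one viral genome.

    ``class_mix`` gives proportions of siRNA-like (21-nt peak, both
    strands), piRNA-like (24-29 nt, 5'-U biased), degradation-like (flat
    18-32 nt) and non-viral (random-sequence) reads."""

    genome: str
    class_mix: dict[str, float]
    n_reads: int
    seed: int = 0
    sirna_length_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SIRNA_LEN))
    sirna_minor_strand: float = 0.45
    pirna_length_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PIRNA_LEN))
    pirna_u_bias: float = 0.8
    pirna_minor_strand: float = 0.2
    degradation_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DEGRADATION_LEN)
    )
    degradation_minor_strand: float = 0.1
    nonviral_length_range: tuple[int, int] = (18, 32)
    duplication_rate: float = 0.0
    quality_violation_frac: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.class_mix) - {"siRNA", "piRNA", "degradation", "nonviral"}
        if unknown:
            raise ValueError(f"unknown read classes {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if self.class_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix sums to {total}, expected 1")
        for dist in (self.sirna_length_dist, self.pirna_length_dist, self.degradation_length_dist):
            if any(p < 0 for p in dist.values()):
                raise ValueError("length distribution probabilities must be >= 0")
        if max(
            max(self.sirna_length_dist), max(self.pirna_length_dist),
            max(self.degradation_length_dist), self.nonviral_length_range[1],
        ) > len(self.genome):
            raise ValueError("read length exceeds genome length")


@dataclass
class LibraryTruth:
    """Per-read provenance for a simulated library."""

    classes: list[str]
    strands: list[str]
    positions: list[int]  # -1 for nonviral reads
    n_distinct_sequences: int
    class_counts: dict[str, int]
    spec_seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _draw_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = sorted(dist)
    probs = np.array([dist[L] for L in lengths], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(lengths, p=probs))


def _viral_read(
    rng: np.random.Generator,
    genome: str,
    length: int,
    minor_strand_p: float,
    force_u: bool,
) -> tuple[str, str, int]:
    """Draw one genome-derived read: (sequence as sequenced, strand, pos).

    ``force_u`` requests a 5'-U read by rejection sampling over positions,
    so reads stay exact genome substrings."""
    L = len(genome)
    strand = "-" if rng.random() < minor_strand_p else "+"
    for _ in range(2000):
        pos = int(rng.integers(0, L - length + 1))
        frag = genome[pos : pos + length]
        seq = revcomp(frag) if strand == "-" else frag
        if not force_u or seq[0] == "T":
            return seq, strand, pos
    return seq, strand, pos  # genome lacks suitable sites; return last draw


def simulate_srna_library(spec: SrnaLibrarySpec) -> tuple[list[SmallRead], LibraryTruth]:
    """Generate a labelled library. Duplication is applied last: a
    ``duplication_rate`` fraction of the library re-emits earlier reads."""
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_mix)
    if spec.n_reads and classes:
        counts = rng.multinomial(spec.n_reads, [spec.class_mix[c] for c in classes])
    else:
        counts = [0] * len(classes)
    reads: list[SmallRead] = []
    truth_classes: list[str] = []
    truth_strands: list[str] = []
    truth_positions: list[int] = []

    order: list[tuple[str, int]] = []
    for cls, n in zip(classes, counts):
        order.extend((cls, i) for i in range(int(n)))
    # interleave classes deterministically
    perm = rng.permutation(len(order))
    order = [order[i] for i in perm]

    for idx, (cls, _) in enumerate(order):
        if cls == "siRNA":
            length = _draw_length(rng, spec.sirna_length_dist)
            seq, strand, pos = _viral_read(rng, spec.genome, length, spec.sirna_minor_strand, False)
        elif cls == "piRNA":
            length = _draw_length(rng, spec.pirna_length_dist)
            force_u = bool(rng.random() < spec.pirna_u_bias)
            seq, strand, pos = _viral_read(rng, spec.genome, length, spec.pirna_minor_strand, force_u)
        elif cls == "degradation":
            length = _draw_length(rng, spec.degradation_length_dist)
            seq, strand, pos = _viral_read(
                rng, spec.genome, length, spec.degradation_minor_strand, False
            )
        else:  # nonviral
            lo, hi = spec.nonviral_length_range
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(list(BASES), size=length))
            strand, pos = "+", -1
        reads.append(SmallRead(id=f"read{idx}", sequence=seq, qualities=None))
        truth_classes.append(cls)
        truth_strands.append(strand)
        truth_positions.append(pos)

    # duplication pass
    n_dup = int(round(spec.duplication_rate * len(reads)))
    if n_dup and reads:
        keep = len(reads) - n_dup
        sources = rng.integers(0, max(keep, 1), size=n_dup)
        base = reads[:keep]
        reads = base + [
            SmallRead(id=f"dup{i}", sequence=base[s].sequence) for i, s in enumerate(sources)
        ]
        truth_classes = truth_classes[:keep] + [truth_classes[s] for s in sources]
        truth_strands = truth_strands[:keep] + [truth_strands[s] for s in sources]
        truth_positions = truth_positions[:keep] + [truth_positions[s] for s in sources]

    # optional planted quality violations, realized when writing FASTQ
    qualities = None
    if spec.quality_violation_frac > 0:
        n_bad = int(round(spec.quality_violation_frac * len(reads)))
        bad = set(rng.choice(len(reads), size=n_bad, replace=False)) if n_bad else set()
        out = []
        for i, r in enumerate(reads):
            if i in bad:
                qual = tuple([2] * r.length)  # every base low-quality
            else:
                qual = tuple([30] * r.length)
            out.append(SmallRead(id=r.id, sequence=r.sequence, qualities=qual))
        reads = out

    truth = LibraryTruth(
        classes=truth_classes,
        strands=truth_strands,
        positions=truth_positions,
        n_distinct_sequences=len({r.sequence for r in reads}),
        class_counts={c: truth_classes.count(c) for c in classes},
        spec_seed=spec.seed,
    )
    return reads, truth


def write_fastq(reads: Sequence[SmallRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.qualities is not None:
                qual = "".join(chr(q + 33) for q in r.qualities)
            else:
                qual = FASTQ_QUALITY_CHAR * r.length
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def simulate_qpcr(
    true_copies: float,
    curve: StandardCurve,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
    target: str = "",
) -> QpcrMeasurement:
    """Ct drawn on the standard-curve line with Gaussian cycle noise."""
    if true_copies <= 0:
        raise ValueError("true_copies must be > 0")
    rng = np.random.default_rng(seed)
    ct = curve.intercept + curve.slope * np.log10(true_copies)
    if noise_sd > 0:
        ct += rng.normal(0.0, noise_sd)
    return QpcrMeasurement(sample_id, target or curve.target, float(ct),
                           efficiency_E=min(curve.implied_efficiency, 2.2))


@dataclass
class ContigTruth:
    """Planted attributes and implied verdict for one simulated contig."""

    contig_id: str
    has_viral_hit: bool
    is_short: bool
    has_host_hit: bool
    has_orf: bool
    kept: bool
    reasons: list[str]


def _no_orf_sequence(length: int) -> str:
    return (NO_ORF_MOTIF * (length // len(NO_ORF_MOTIF) + 1))[:length]


def _orf_bearing_sequence(rng: np.random.Generator, length: int, min_codons: int = 40) -> str:
    """Random sequence with one explicitly planted ORF."""
    seq = list(rng.choice(list(BASES), size=length))
    non_stop = [c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
                if c not in ("TAA", "TAG", "TGA")]
    orf = "ATG" + "".join(rng.choice(non_stop) for _ in range(min_codons)) + "TAA"
    start = int(rng.integers(0, length - len(orf) + 1))
    start -= start % 3  # keep frame deterministic, not required but tidy
    seq[start : start + len(orf)] = list(orf)
    return "".join(seq)


def simulate_contig_set(
    n: int,
    frac_viral: float = 0.7,
    frac_short: float = 0.3,
    frac_host: float = 0.2,
    frac_no_orf: float = 0.2,
    seed: int = 0,
) -> tuple[list[Contig], list[HomologyHit], list[HomologyHit], list[ContigTruth]]:
    """Contig set plus viral/host hit tables with planted ground truth.

    Each attribute is drawn independently per contig; hit e-values fall on
    the appropriate side of the 1e-5 (viral) and 1e-100 (host) thresholds,
    with near-threshold negatives included."""
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    viral_hits: list[HomologyHit] = []
    host_hits: list[HomologyHit] = []
    truths: list[ContigTruth] = []

    def _hit(cid: str, subject: str, length: int, evalue: float) -> HomologyHit:
        end = int(rng.integers(60, max(61, length)))
        return HomologyHit(
            query_id=cid, subject_id=subject,
            pident=float(np.round(rng.uniform(30, 100), 2)),
            aln_length=end - 1, mismatch=0, gapopen=0,
            aln_start=1, aln_end=end, sstart=1, send=end,
            evalue=evalue, bitscore=float(np.round(rng.uniform(50, 900), 1)),
        )

    for i in range(n):
        cid = f"contig_{i:04d}"
        has_viral = bool(rng.random() < frac_viral)
        is_short = bool(rng.random() < frac_short)
        has_host = bool(rng.random() < frac_host)
        no_orf = bool(rng.random() < frac_no_orf)

        length = int(rng.integers(300, 2000)) if is_short else int(rng.integers(2000, 4001))
        seq = _no_orf_sequence(length) if no_orf else _orf_bearing_sequence(rng, length)
        contigs.append(Contig(cid, seq))

        if has_viral:
            viral_hits.append(_hit(cid, "viral_subject", length, 10.0 ** -rng.uniform(6, 50)))
        elif rng.random() < 0.5:  # sub-threshold distractor hit
            viral_hits.append(_hit(cid, "viral_subject", length, 10.0 ** -rng.uniform(0, 4.9)))
        if has_host:
            host_hits.append(_hit(cid, "host_genome", length, 10.0 ** -rng.uniform(101, 180)))
        elif rng.random() < 0.5:
            host_hits.append(_hit(cid, "host_genome", length, 10.0 ** -rng.uniform(5, 99)))

        reasons = []
        if not has_viral:
            reasons.append("no_viral_hit")
        if is_short:
            reasons.append("too_short")
        if has_host:
            reasons.append("host_genome")
        if no_orf:
            reasons.append("no_orf")
        truths.append(
            ContigTruth(cid, has_viral, is_short, has_host, not no_orf, not reasons, reasons)
        )
    return contigs, viral_hits, host_hits, truths


def write_contig_truth(truths: Sequence[ContigTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\thas_viral_hit\tis_short\thas_host_hit\thas_orf\tkept\treasons\n")
        for t in truths:
            fh.write(
                f"{t.contig_id}\t{t.has_viral_hit}\t{t.is_short}\t{t.has_host_hit}\t"
                f"{t.has_orf}\t{t.kept}\t{','.join(t.reasons)}\n"
            )
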