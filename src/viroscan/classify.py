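"""Classify per-virus small-RNA profiles into signature classes.

Decision rule, evaluated in order on a profile of unique mapped reads:

1. fewer than ``min_reads`` unique mapped reads        -> absent
2. a read-length peak at 21 +/- 1 nt holding at least ``min_peak_fraction``
   of reads AND both strands represented (minor strand fraction >=
   ``min_minor_strand``)                               -> siRNA
3. modal length within 24-29 nt AND 5'-U fraction of 24-29 nt reads >=
   ``min_u_bias``                                      -> piRNA
4. otherwise                                           -> degradation

All thresholds are explicit, configurable, and echoed into every call;
the underlying signals are qualitative in origin, so no threshold is a
measured constant.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

from .profile import VsRNAProfile

logger = logging.getLogger(__name__)

LABELS = ("siRNA", "piRNA", "degradation", "absent")

PIRNA_LEN_RANGE = (24, 29)


@dataclass(frozen=True)
class Thresholds:
    min_reads: int = 50
    peak_center: int = 21
    peak_halfwidth: int = 1
    min_peak_fraction: float = 0.4
    min_minor_strand: float = 0.1
    min_u_bias: float = 0.5
    min_breadth: float = 0.5


@dataclass(frozen=True)
class SignatureCall:
    virus_abbrev: str
    sample_id: str
    label: str
    peak_length: int | None
    peak_fraction: float
    minor_strand_fraction: float
    u_bias: float
    breadth: float
    n_unique_mapped: int
    thresholds: Thresholds = Thresholds()


def _modal_length(hist: dict[tuple[int, str], int]) -> int | None:
    """Modal read length over both strands; ties break toward the smaller
    length for deterministic reporting."""
    by_len: dict[int, int] = {}
    for (length, _), count in hist.items():
        by_len[length] = by_len.get(length, 0) + count
    if not by_len:
        return None
    return min(by_len, key=lambda L: (-by_len[L], L))


def classify_profile(
    profile: VsRNAProfile, thresholds: Thresholds | None = None
) -> SignatureCall:
    th = thresholds or Thresholds()
    hist = profile.length_hist
    n = profile.n_unique_mapped
    if sum(hist.values()) != n:
        raise ValueError(
            f"profile histogram total {sum(hist.values())} != n_unique_mapped {n}"
        )

    total = max(n, 1)
    lo = th.peak_center - th.peak_halfwidth
    hi = th.peak_center + th.peak_halfwidth
    peak_count = sum(c for (L, _), c in hist.items() if lo <= L <= hi)
    peak_fraction = peak_count / total
    plus, minus = profile.strand_counts()
    minor = min(plus, minus) / total
    pir_lo, pir_hi = PIRNA_LEN_RANGE
    pir_total = 0
    pir_u = 0
    for (L, strand), comp in profile.first_base_comp.items():
        if pir_lo <= L <= pir_hi:
            pir_total += sum(comp.values())
            pir_u += comp.get("U", 0)
    u_bias = pir_u / pir_total if pir_total else 0.0
    modal = _modal_length(hist)

    if n < th.min_reads:
        label = "absent"
    elif peak_fraction >= th.min_peak_fraction and minor >= th.min_minor_strand:
        label = "siRNA"
    elif modal is not None and pir_lo <= modal <= pir_hi and u_bias >= th.min_u_bias:
        label = "piRNA"
    else:
        label = "degradation"

    logger.debug(
        "classify %s/%s: n=%d peak=%.3f minor=%.3f u=%.3f modal=%s -> %s",
        profile.virus_abbrev,
        profile.sample_id,
        n,
        peak_fraction,
        minor,
        u_bias,
        modal,
        label,
    )
    return SignatureCall(
        virus_abbrev=profile.virus_abbrev,
        sample_id=profile.sample_id,
        label=label,
        peak_length=modal,
        peak_fraction=peak_fraction,
        minor_strand_fraction=minor,
        u_bias=u_bias,
        breadth=profile.uniformity,
        n_unique_mapped=n,
        thresholds=th,
    )


def classify_library(
    reads,
    genomes: Sequence[tuple[str, str]],
    sample_id: str = "",
    thresholds: Thresholds | None = None,
    max_mismatch: int = 0,
) -> dict[str, SignatureCall]:
    """Full pipeline for one cleaned library: map -> collapse -> profile ->
    classify, one call per genome."""
    from .profile import collapse_reads, profile_virus
    from .srnamap import build_index, map_reads

    index = build_index(genomes)
    mapped, stats = map_reads(reads, index, max_mismatch=max_mismatch)
    n_unique_library = stats.n_unique_input
    by_virus: dict[str, list] = {name: [] for name, _ in genomes}
    for m in mapped:
        by_virus[m.virus_abbrev].append(m)
    calls = {}
    lengths = dict((name, len(seq)) for name, seq in genomes)
    for name, ms in by_virus.items():
        prof = profile_virus(
            ms, lengths[name], n_unique_library, virus_abbrev=name, sample_id=sample_id
        )
        calls[name] = classify_profile(prof, thresholds)
    return calls


def signature_power_curve(
    genome: str,
    n_grid: Sequence[int],
    reps: int,
    seed: int,
    thresholds: Thresholds | None = None,
    classes: Sequence[str] = LABELS,
) -> list[dict]:
    """Recovery rate of each generating class across library depths.

    For each (class, n) cell, ``reps`` libraries are simulated with the
    generator defaults for that class and pushed through the full pipeline;
    recovery is the fraction of runs whose call equals the class ('absent'
    libraries contain only non-viral reads)."""
    from .simulate import SrnaLibrarySpec, simulate_srna_library

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    run = 0
    for cls in classes:
        for n in n_grid:
            hits = 0
            for rep in range(reps):
                mix = {"siRNA": 0.0, "piRNA": 0.0, "degradation": 0.0, "nonviral": 0.0}
                mix["nonviral" if cls == "absent" else cls] = 1.0
                spec = SrnaLibrarySpec(
                    genome=genome, class_mix=mix, n_reads=n, seed=seed + run
                )
                run += 1
                reads, _ = simulate_srna_library(spec)
                calls = classify_library(
                    reads, [("V", genome)], sample_id=f"{cls}/{n}/{rep}", thresholds=thresholds
                )
                if calls["V"].label == cls:
                    hits += 1
            rows.append({"class": cls, "n_reads": n, "reps": reps, "recovery": hits / reps})
    return rows


def write_calls(calls: Sequence[SignatureCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "virus",
                "sample",
                "label",
                "peak_length",
                "peak_fraction",
                "minor_strand_fraction",
                "u_bias",
                "breadth",
                "n_unique_mapped",
                "thresholds",
            ]
        )
        for c in calls:
            w.writerow(
                [
                    c.virus_abbrev,
                    c.sample_id,
                    c.label,
                    "" if c.peak_length is None else c.peak_length,
                    f"{c.peak_fraction:.4f}",
                    f"{c.minor_strand_fraction:.4f}",
                    f"{c.u_bias:.4f}",
                    f"{c.breadth:.4f}",
                    c.n_unique_mapped,
                    ";".join(f"{k}={v}" for k, v in asdict(c.thresholds).items()),
                ]
            )
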