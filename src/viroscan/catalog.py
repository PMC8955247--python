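"""Virus catalogue: typed records, TSV/FASTA readers and writers, summaries.

The packaged catalogue ships as a TSV (one row per genome record; segmented
viruses contribute one row per segment). Accessions are opaque strings and
are never resolved against any remote registry.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

from ._util import read_fasta, write_fasta


class GenomeType(str, Enum):
    positive_ssRNA = "positive_ssRNA"
    negative_ssRNA = "negative_ssRNA"
    dsRNA = "dsRNA"


REQUIRED_COLUMNS = (
    "virus_name",
    "abbreviation",
    "genome_type",
    "family",
    "segment_label",
    "genome_length",
    "accession",
)


class CatalogSchemaError(ValueError):
    """Catalogue table is missing required columns or has bad values."""


class CatalogIntegrityError(ValueError):
    """Catalogue metadata disagrees with the accompanying sequences."""


@dataclass(frozen=True)
class VirusRecord:
    """One genome (or genome segment) of a catalogued virus."""

    virus_name: str
    abbreviation: str
    genome_type: GenomeType
    family: str
    segment_label: str | None
    genome_length: int
    accession: str

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise CatalogSchemaError(
                f"{self.abbreviation}: genome_length must be > 0, got {self.genome_length}"
            )


@dataclass(frozen=True)
class CatalogSummary:
    n_viruses: int
    n_records: int
    counts_by_genome_type: dict[GenomeType, int]
    min_genome_length: int
    max_genome_length: int
    smallest_virus: str


def packaged_catalog_path() -> Path:
    """Path of the catalogue TSV shipped inside the package."""
    return Path(str(resources.files("viroscan").joinpath("data/virus_catalog.tsv")))


def load_catalog(
    metadata_table: str | Path, genomes: str | Path | None = None
) -> list[VirusRecord]:
    """Read a catalogue TSV, optionally cross-checking genome lengths vs FASTA.

    When ``genomes`` is given, each FASTA record whose id matches a catalogue
    accession must have exactly the tabulated length.
    """
    records: list[VirusRecord] = []
    with open(metadata_table, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in cols]
        if missing:
            raise CatalogSchemaError(f"catalogue TSV missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                gtype = GenomeType(row["genome_type"])
            except ValueError as exc:
                raise CatalogSchemaError(
                    f"line {i}: unknown genome_type {row['genome_type']!r}"
                ) from exc
            try:
                length = int(row["genome_length"])
            except ValueError as exc:
                raise CatalogSchemaError(
                    f"line {i}: genome_length {row['genome_length']!r} is not an integer"
                ) from exc
            records.append(
                VirusRecord(
                    virus_name=row["virus_name"],
                    abbreviation=row["abbreviation"],
                    genome_type=gtype,
                    family=row["family"],
                    segment_label=row["segment_label"] or None,
                    genome_length=length,
                    accession=row["accession"],
                )
            )
    seen: set[tuple[str, str | None]] = set()
    for rec in records:
        key = (rec.abbreviation, rec.segment_label)
        if key in seen:
            raise CatalogSchemaError(f"duplicate record for {key}")
        seen.add(key)
    if genomes is not None:
        lengths = {name: len(seq) for name, seq in read_fasta(genomes)}
        for rec in records:
            if rec.accession in lengths and lengths[rec.accession] != rec.genome_length:
                raise CatalogIntegrityError(
                    f"{rec.accession}: FASTA length {lengths[rec.accession]} != "
                    f"catalogue length {rec.genome_length}"
                )
    return records


def write_catalog(records: list[VirusRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.virus_name,
                    rec.abbreviation,
                    rec.genome_type.value,
                    rec.family,
                    rec.segment_label or "",
                    rec.genome_length,
                    rec.accession,
                ]
            )


def summarize_catalog(records: list[VirusRecord]) -> CatalogSummary:
    """Counts and length extrema. Genome-type counts are per virus, not per
    segment. Length extrema are per VIRUS, summing segment lengths for
    segmented genomes: individual segments of a multipartite virus can be
    shorter than the smallest complete genome, and the smallest-virus claim
    refers to whole genomes."""
    if not records:
        raise ValueError("cannot summarize an empty catalogue")
    gtype_by_virus: dict[str, GenomeType] = {}
    abbrev_by_virus: dict[str, str] = {}
    total_by_virus: dict[str, int] = {}
    for rec in records:
        gtype_by_virus[rec.virus_name] = rec.genome_type
        abbrev_by_virus[rec.virus_name] = rec.abbreviation
        total_by_virus[rec.virus_name] = (
            total_by_virus.get(rec.virus_name, 0) + rec.genome_length
        )
    counts = Counter(gtype_by_virus.values())
    smallest_name = min(sorted(total_by_virus), key=total_by_virus.get)
    return CatalogSummary(
        n_viruses=len(gtype_by_virus),
        n_records=len(records),
        counts_by_genome_type={t: counts.get(t, 0) for t in GenomeType},
        min_genome_length=total_by_virus[smallest_name],
        max_genome_length=max(total_by_virus.values()),
        smallest_virus=abbrev_by_virus[smallest_name],
    )


def records_for(records: list[VirusRecord], abbreviation: str) -> list[VirusRecord]:
    """All records (segments) of one virus, by abbreviation."""
    return [r for r in records if r.abbreviation == abbreviation]


def write_placeholder_genomes(records: list[VirusRecord], path: str | Path, seed: int = 20220317) -> None:
    """Emit deterministic pseudo-random stand-in sequences of catalogued
    lengths, keyed by accession, so length-integrity checks can run without
    real sequence data."""
    from .simulate import simulate_genome

    out = []
    for i, rec in enumerate(sorted(records, key=lambda r: r.accession)):
        out.append((rec.accession, simulate_genome(rec.genome_length, gc=0.5, seed=seed + i)))
    write_fasta(path, out)
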