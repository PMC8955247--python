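import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import naive_scan, rc
from viroscan.simulate import SrnaLibrarySpec, simulate_srna_library, write_fastq
from viroscan.srnamap import (
    DuplicateGenomeError,
    FastqParseError,
    MappedRead,
    SmallRead,
    build_index,
    clean_reads,
    map_reads,
    parse_fastq,
    write_mappings,
    write_sam,
)


def _read(seq, quals=None, rid="r"):
    return SmallRead(id=rid, sequence=seq, qualities=quals)


# ---------------------------------------------------------------------------
# cleaning

def test_short_read_removed_for_length():
    kept, stats = clean_reads([_read("A" * 8 + "CGT" * 3)])  # 17 nt
    assert kept == []
    assert stats.removed_length == 1


def test_33nt_read_removed_for_length():
    kept, stats = clean_reads([_read("ACG" * 11)])
    assert stats.removed_length == 1


def test_low_quality_fraction_removed():
    # 5 of 21 bases below Q20 -> 23.8% > 20%
    quals = tuple([30] * 16 + [10] * 5)
    kept, stats = clean_reads([_read("ACGTA" * 4 + "C", quals)])
    assert kept == []
    assert stats.removed_quality == 1


def test_exactly_20pct_low_quality_is_kept():
    quals = tuple([30] * 16 + [10] * 4)  # 4/20 = 20%, rule is strict >
    kept, _ = clean_reads([_read("ACGTA" * 4, quals)])
    assert len(kept) == 1


def test_homopolymer_removed_as_low_complexity():
    kept, stats = clean_reads([_read("A" * 20)])
    assert stats.removed_low_complexity == 1


def test_reads_without_qualities_skip_quality_rule():
    kept, _ = clean_reads([_read("ACGT" * 5)])
    assert len(kept) == 1


def test_planted_violations_are_exactly_the_removals(genome_10k):
    spec = SrnaLibrarySpec(
        genome=genome_10k,
        class_mix={"siRNA": 1.0},
        n_reads=1000,
        seed=9,
        quality_violation_frac=0.1,
    )
    reads, _ = simulate_srna_library(spec)
    bad = {r.id for r in reads if all(q < 20 for q in r.qualities)}
    kept, stats = clean_reads(reads)
    assert {r.id for r in kept} == {r.id for r in reads} - bad
    assert stats.removed_quality == len(bad) == 100


def test_fastq_round_trip_and_parse_error(tmp_path, genome_10k):
    spec = SrnaLibrarySpec(genome=genome_10k, class_mix={"siRNA": 1.0}, n_reads=50, seed=1)
    reads, _ = simulate_srna_library(spec)
    p = tmp_path / "lib.fastq"
    write_fastq(reads, p)
    parsed = list(parse_fastq(p))
    assert [r.sequence for r in parsed] == [r.sequence for r in reads]

    bad = tmp_path / "bad.fastq"
    bad.write_text("@r1\nACGT\nMISSING_PLUS\nIIII\n")
    with pytest.raises(FastqParseError, match="record"):
        list(parse_fastq(bad))


# ---------------------------------------------------------------------------
# index + mapping

def test_planted_substring_found(genome_1k):
    idx = build_index([("V", genome_1k)])
    hits = idx.lookup(genome_1k[100:121])
    assert ("V", 100, "+", 0) in hits


def test_reverse_complement_found_on_minus_strand(genome_1k):
    idx = build_index([("V", genome_1k)])
    hits = idx.lookup(rc(genome_1k[100:121]))
    assert ("V", 100, "-", 0) in hits


def test_duplicate_genome_abbreviation_rejected(genome_1k):
    with pytest.raises(DuplicateGenomeError):
        build_index([("V", genome_1k), ("V", genome_1k)])


def test_read_with_n_never_maps(genome_1k):
    idx = build_index([("V", genome_1k)])
    q = genome_1k[100:121]
    assert idx.lookup("N" + q[1:], max_mismatch=1) == []


def test_one_mismatch_lookup(genome_1k):
    idx = build_index([("V", genome_1k)])
    q = genome_1k[200:225]
    mutated = ("A" if q[12] != "A" else "C") + q[13:]
    mutated = q[:12] + mutated
    assert idx.lookup(mutated, max_mismatch=0) == [] or q[12] == mutated[12]
    hits = idx.lookup(mutated, max_mismatch=1)
    assert ("V", 200, "+", 1) in hits


@pytest.mark.parametrize("max_mismatch", [0, 1])
def test_lookup_matches_naive_scan(genome_10k, max_mismatch):
    rng = np.random.default_rng(5)
    idx = build_index([("V", genome_10k)])
    for _ in range(120):
        L = int(rng.integers(18, 33))
        kind = rng.integers(0, 4)
        pos = int(rng.integers(0, len(genome_10k) - L + 1))
        q = genome_10k[pos : pos + L]
        if kind == 1:
            q = rc(q)
        elif kind == 2:  # mutate 1-2 positions
            q = list(q)
            for j in rng.integers(0, L, size=int(rng.integers(1, 3))):
                q[j] = "ACGT"[int(rng.integers(0, 4))]
            q = "".join(q)
        elif kind == 3:
            q = "".join(rng.choice(list("ACGT"), size=L))
        got = {(p, s, m) for (_, p, s, m) in idx.lookup(q, max_mismatch)}
        assert got == naive_scan(genome_10k, q, max_mismatch)


def test_mapped_fraction_equals_planted_viral_fraction(genome_10k):
    spec = SrnaLibrarySpec(
        genome=genome_10k,
        class_mix={"siRNA": 0.5, "nonviral": 0.5},
        n_reads=10_000,
        seed=3,
    )
    reads, truth = simulate_srna_library(spec)
    idx = build_index([("V", genome_10k)])
    mapped, stats = map_reads(reads, idx, max_mismatch=0)
    viral_seqs = {r.sequence for r, c in zip(reads, truth.classes) if c == "siRNA"}
    nonviral_seqs = {r.sequence for r, c in zip(reads, truth.classes) if c == "nonviral"}
    mapped_seqs = {m.read_sequence for m in mapped}
    # noiseless exact matching: every viral read maps, no nonviral read does
    assert viral_seqs <= mapped_seqs
    assert not (nonviral_seqs - viral_seqs) & mapped_seqs
    assert stats.n_unique_mapped_any == len(viral_seqs)


def test_every_mapping_revalidates_by_string_comparison(genome_10k):
    spec = SrnaLibrarySpec(
        genome=genome_10k,
        class_mix={"siRNA": 0.8, "degradation": 0.2},
        n_reads=2000,
        seed=8,
    )
    reads, _ = simulate_srna_library(spec)
    mapped, _ = map_reads(reads, build_index([("V", genome_10k)]))
    for m in mapped:
        window = genome_10k[m.position : m.position + len(m.read_sequence)]
        expected = m.read_sequence if m.strand == "+" else rc(m.read_sequence)
        assert window == expected


def test_mapping_is_order_independent(genome_10k):
    spec = SrnaLibrarySpec(genome=genome_10k, class_mix={"siRNA": 1.0}, n_reads=500, seed=4)
    reads, _ = simulate_srna_library(spec)
    idx = build_index([("V", genome_10k)])
    fwd, _ = map_reads(reads, idx)
    rev, _ = map_reads(list(reversed(reads)), idx)
    assert sorted(fwd, key=lambda m: m.read_sequence) == sorted(
        rev, key=lambda m: m.read_sequence
    )


def test_multi_genome_counting_is_per_virus(genome_1k):
    # identical genomes under two names: each unique read counts once per virus
    idx = build_index([("A", genome_1k), ("B", genome_1k)])
    reads = [_read(genome_1k[i : i + 21], rid=f"r{i}") for i in range(0, 100, 10)]
    mapped, stats = map_reads(reads, idx)
    assert stats.unique_mapped_per_virus == {"A": 10, "B": 10}
    assert len(mapped) == 20


def test_unmapped_negative_control(genome_1k):
    idx = build_index([("V", genome_1k)])
    # a read absent from the genome on either strand
    q = "ACGT" * 5
    while q in genome_1k or rc(q) in genome_1k:
        q = "A" + q[:-1]
    mapped, stats = map_reads([_read(q)], idx)
    assert mapped == []
    assert stats.n_unique_unmapped == 1


def test_write_outputs(tmp_path, genome_1k):
    idx = build_index([("V", genome_1k)])
    reads = [_read(genome_1k[5:26]), _read(rc(genome_1k[50:75]))]
    mapped, _ = map_reads(reads, idx)
    write_mappings(mapped, tmp_path / "map.tsv")
    lines = (tmp_path / "map.tsv").read_text().splitlines()
    assert len(lines) == 3 and lines[0].startswith("sequence\t")
    pos_col = [int(line.split("\t")[2]) for line in lines[1:]]
    assert set(pos_col) == {6, 51}  # 1-based in files
    write_sam(mapped, [("V", genome_1k)], tmp_path / "map.sam")
    sam = (tmp_path / "map.sam").read_text()
    assert "@SQ\tSN:V\tLN:1000" in sam


@given(st.lists(st.text(alphabet="ACGT", min_size=18, max_size=32), max_size=30))
@settings(max_examples=30, deadline=None)
def test_lookup_determinism(queries):
    genome = ("ACGT" * 300)[:1000]
    idx = build_index([("V", genome)])
    for q in queries:
        assert idx.lookup(q, 1) == idx.lookup(q, 1)
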