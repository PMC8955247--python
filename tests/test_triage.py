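import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_orfs, rc
from viroscan.simulate import simulate_contig_set, simulate_genome
from viroscan.triage import (
    Contig,
    HomologyHit,
    ReferentialError,
    TriageParams,
    find_orfs,
    read_hit_table,
    terminal_coverage_check,
    triage_contigs,
    write_verdicts,
)


def _hit(query_id, evalue, subject="s"):
    return HomologyHit(query_id, subject, 90.0, 100, 0, 0, 1, 100, 1, 100, evalue, 200.0)


# ---------------------------------------------------------------------------
# ORF scanner

def test_minimal_start_stop_orf():
    calls = find_orfs(Contig("c", "ATGAAATAA"), min_aa_length=2, require_start=True)
    assert len(calls) == 1
    (orf,) = calls
    assert (orf.frame, orf.start, orf.end, orf.aa_length) == (1, 0, 9, 2)
    assert orf.has_stop


def test_strand_symmetry_of_minimal_orf():
    fwd = find_orfs(Contig("c", "ATGAAATAA"), 2, True)
    rev = find_orfs(Contig("c", rc("ATGAAATAA")), 2, True)
    assert [(o.start, o.end, o.aa_length) for o in rev] == [
        (o.start, o.end, o.aa_length) for o in fwd
    ]
    assert rev[0].frame == -1


def test_all_n_sequence_has_no_orfs():
    assert find_orfs(Contig("c", "N" * 300), 1) == []


def test_n_codons_break_frames():
    # 30 codons, one N codon in the middle of frame +1
    seq = "ATG" + "GCA" * 10 + "NNN" + "GCA" * 10 + "TAA"
    frames_plus1 = [o for o in find_orfs(Contig("c", seq), 5) if o.frame == 1]
    assert all("N" not in seq[o.start : o.end] for o in frames_plus1)


def test_empty_sequence_is_error():
    with pytest.raises(ValueError):
        find_orfs(Contig("c", ""), 1)


@pytest.mark.parametrize("require_start", [False, True])
def test_orfs_match_brute_force_on_random_sequences(require_start):
    rng = np.random.default_rng(42)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        got = {
            (o.frame, o.start, o.end, o.aa_length, o.has_stop)
            for o in find_orfs(Contig("c", seq), 5, require_start)
        }
        assert got == brute_force_orfs(seq, 5, require_start)


def test_orfs_match_brute_force_with_ns():
    rng = np.random.default_rng(7)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        got = {
            (o.frame, o.start, o.end, o.aa_length, o.has_stop)
            for o in find_orfs(Contig("c", seq), 3)
        }
        assert got == brute_force_orfs(seq, 3, False)


def test_orfs_sorted_by_length_desc(genome_1k):
    calls = find_orfs(Contig("c", genome_1k), 5)
    assert [o.aa_length for o in calls] == sorted(
        (o.aa_length for o in calls), reverse=True
    )


# ---------------------------------------------------------------------------
# triage cascade

def test_short_contig_discarded_with_length_reason():
    contig = Contig("c1", simulate_genome(1999, seed=3)[:1999])
    verdicts = triage_contigs([contig], [_hit("c1", 1e-20)], [])
    assert not verdicts[0].kept
    assert verdicts[0].reasons == ["too_short"]


def test_host_hit_discards_long_viral_contig():
    contig = Contig("c1", simulate_genome(5000, seed=4))
    verdicts = triage_contigs([contig], [_hit("c1", 1e-20)], [_hit("c1", 1e-120)])
    assert verdicts[0].reasons == ["host_genome"]


def test_subthreshold_host_hit_is_ignored():
    contig = Contig("c1", simulate_genome(5000, seed=4))
    verdicts = triage_contigs([contig], [_hit("c1", 1e-20)], [_hit("c1", 1e-50)])
    assert verdicts[0].kept


def test_contig_without_any_hit_fails_first_filter():
    contig = Contig("c1", simulate_genome(5000, seed=5))
    verdicts = triage_contigs([contig], [], [])
    assert verdicts[0].reasons == ["no_viral_hit"]


def test_unknown_contig_in_hits_is_referential_error():
    with pytest.raises(ReferentialError):
        triage_contigs([Contig("c1", "ACGT" * 1000)], [_hit("ghost", 1e-20)], [])


def test_reasons_accumulate_in_filter_order():
    contig = Contig("c1", ("AACT" * 500))  # 2000 nt but no ORF
    verdicts = triage_contigs([contig], [], [_hit("c1", 1e-150)])
    assert verdicts[0].reasons == ["no_viral_hit", "host_genome", "no_orf"]


def _truth_reasons(t):
    reasons = []
    if not t.has_viral_hit:
        reasons.append("no_viral_hit")
    if t.is_short:
        reasons.append("too_short")
    if t.has_host_hit:
        reasons.append("host_genome")
    if not t.has_orf:
        reasons.append("no_orf")
    return reasons


def test_triage_matches_planted_truth_exactly():
    contigs, viral, host, truth = simulate_contig_set(n=200, seed=7)
    verdicts = triage_contigs(contigs, viral, host)
    for v, t in zip(verdicts, truth):
        assert v.contig_id == t.contig_id
        assert v.kept == t.kept
        assert v.reasons == _truth_reasons(t)


def test_threshold_sweeps_are_monotone():
    contigs, viral, host, _ = simulate_contig_set(n=200, seed=7)
    kept_sets = []
    for min_length in (1000, 2000, 4000):
        verdicts = triage_contigs(contigs, viral, host, TriageParams(min_length=min_length))
        kept_sets.append({v.contig_id for v in verdicts if v.kept})
    assert kept_sets[2] <= kept_sets[1] <= kept_sets[0]
    for emax in (1e-5, 1e-20, 1e-40):
        verdicts = triage_contigs(contigs, viral, host, TriageParams(viral_evalue_max=emax))
        kept = {v.contig_id for v in verdicts if v.kept}
        assert kept <= kept_sets[1] or emax == 1e-5


def test_verdict_tsv_round_trip_fields(tmp_path):
    contigs, viral, host, _ = simulate_contig_set(n=20, seed=1)
    verdicts = triage_contigs(contigs, viral, host)
    out = tmp_path / "verdicts.tsv"
    write_verdicts(verdicts, out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == [
        "contig_id", "kept", "reasons", "length", "best_viral_evalue", "best_host_evalue",
    ]
    assert len(lines) == 21


def test_hit_table_round_trip(tmp_path):
    _, viral, _, _ = simulate_contig_set(n=30, seed=2)
    p = tmp_path / "hits.tsv"
    with open(p, "w") as fh:
        for h in viral:
            fh.write("\t".join(str(x) for x in [
                h.query_id, h.subject_id, h.pident, h.aln_length, h.mismatch,
                h.gapopen, h.aln_start, h.aln_end, h.sstart, h.send, h.evalue,
                h.bitscore]) + "\n")
    assert read_hit_table(p) == viral


def test_malformed_hit_table_names_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("a\tb\tc\n")
    with pytest.raises(ValueError, match="line 1"):
        read_hit_table(p)


# ---------------------------------------------------------------------------
# terminal coverage

def test_uniform_coverage_passes():
    ok, diag = terminal_coverage_check([10] * 400, end_window=50, min_ratio=0.2)
    assert ok
    assert diag["mean_5prime"] == diag["mean_3prime"] == 10.0


def test_bare_five_prime_end_fails():
    depth = [0] * 100 + [10] * 900
    ok, _ = terminal_coverage_check(depth, end_window=100, min_ratio=0.2)
    assert not ok


def test_all_zero_depth_reports_zero_coverage():
    ok, diag = terminal_coverage_check([0] * 200, end_window=50)
    assert not ok
    assert diag.get("zero_coverage")


def test_depth_too_short_is_error():
    with pytest.raises(ValueError):
        terminal_coverage_check([1] * 99, end_window=50)


@given(
    depth=st.lists(st.integers(min_value=0, max_value=50), min_size=120, max_size=300),
    window=st.integers(min_value=10, max_value=60),
)
@settings(max_examples=50, deadline=None)
def test_terminal_coverage_matches_direct_recomputation(depth, window):
    arr = np.array(depth, float)
    ok, diag = terminal_coverage_check(depth, end_window=window, min_ratio=0.2)
    if arr.mean() == 0:
        assert not ok
    else:
        expected = (
            arr[:window].mean() >= 0.2 * arr.mean()
            and arr[-window:].mean() >= 0.2 * arr.mean()
        )
        assert ok == expected
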