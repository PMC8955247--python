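"""Independent oracles used by the test suite.

These deliberately avoid the package's own scanning/matching code paths:
the ORF oracle enumerates every triplet window, the mapping oracle slides a
numpy window across the whole genome, and the qPCR oracle works in the log
domain. Keep them naive."""

from __future__ import annotations

import math

import numpy as np

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STOPS = {"TAA", "TAG", "TGA"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def _frame_orfs(s: str, off: int, min_aa: int, require_start: bool):
    """Enumerate candidate (start, end, aa, has_stop) in one forward frame of
    ``s`` by checking every codon-aligned window for ORF-hood and maximality."""
    codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
    n = len(codons)

    def coding(c):  # codon usable inside an ORF
        return "N" not in c and c not in STOPS

    def breaker(c):  # codon that ends the previous segment
        return "N" in c or c in STOPS

    out = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            body, last = codons[i : j - 1], codons[j - 1]
            if not all(coding(c) for c in body):
                continue
            if last in STOPS:
                has_stop, aa = True, (j - i) - 1
            elif coding(last):
                # maximal on the right: no further codon, or next is a breaker
                # that is NOT a stop (a stop would be absorbed into the ORF)
                if j < n and not ("N" in codons[j]):
                    continue
                has_stop, aa = False, j - i
            else:
                continue
            # maximal / anchored on the left
            if require_start:
                if codons[i] != "ATG":
                    continue
                k = i - 1
                anchored = True
                while k >= 0 and not breaker(codons[k]):
                    if codons[k] == "ATG":
                        anchored = False
                        break
                    k -= 1
                if not anchored:
                    continue
            else:
                if i > 0 and not breaker(codons[i - 1]):
                    continue
            if aa >= min_aa:
                out.append((off + 3 * i, off + 3 * j, aa, has_stop))
    return out


def brute_force_orfs(seq: str, min_aa: int, require_start: bool):
    """All six-frame ORFs as a set of (frame, start, end, aa, has_stop) in
    forward-strand coordinates."""
    seq = seq.upper()
    L = len(seq)
    found = set()
    for off in range(3):
        for s, e, aa, stop in _frame_orfs(seq, off, min_aa, require_start):
            found.add((off + 1, s, e, aa, stop))
    rcs = rc(seq)
    for off in range(3):
        for s, e, aa, stop in _frame_orfs(rcs, off, min_aa, require_start):
            found.add((-(off + 1), L - e, L - s, aa, stop))
    return found


def naive_scan(genome: str, query: str, max_mismatch: int):
    """Every placement of query on either strand with <= max_mismatch
    substitutions, via a full sliding-window comparison."""
    if "N" in query:
        return set()
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    out = set()
    for strand, q in (("+", query), ("-", rc(query))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        if len(qa) > len(g):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, len(qa))
        mm = (windows != qa).sum(axis=1)
        for pos in np.nonzero(mm <= max_mismatch)[0]:
            out.add((int(pos), strand, int(mm[pos])))
    return out


def qpcr_ratio_log_domain(ct_v: float, ct_r: float, e_v: float, e_r: float) -> float:
    return math.exp(math.log(e_r) * ct_r - math.log(e_v) * ct_v)
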