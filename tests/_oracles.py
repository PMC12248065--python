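"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately share no code with the package implementation: simple
quadratic scans and exact rational arithmetic only.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def cluster_scan_oracle(coverage, min_per_base=10, min_total=20):
    """Maximal runs of positions with coverage > min_per_base, totalling
    >= min_total reads: list of (start, end, total) offsets."""
    runs = []
    i = 0
    n = len(coverage)
    while i < n:
        if coverage[i] > min_per_base:
            j = i
            while j < n and coverage[j] > min_per_base:
                j += 1
            total = int(sum(coverage[i:j]))
            if total >= min_total:
                runs.append((i, j, total))
            i = j
        else:
            i += 1
    return runs


def overlap_oracle(intervals_a, intervals_b, stranded=True):
    """All-pairs overlap scan: returns {(i, j)} of overlapping index pairs."""
    hits = set()
    for i, a in enumerate(intervals_a):
        for j, b in enumerate(intervals_b):
            if a.chrom != b.chrom:
                continue
            if stranded and a.strand != b.strand:
                continue
            if a.start < b.end and b.start < a.end:
                hits.add((i, j))
    return hits


def fisher_two_tail_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-tailed Fisher exact p by full hypergeometric enumeration.

    Exact rational arithmetic over all tables with the observed margins; a
    table is counted when its probability does not exceed the observed
    table's (with the conventional 1e-7 relative tie tolerance).
    """
    K = k1 + k2
    N = n1 + n2
    denom = comb(N, K)

    def prob(a: int) -> Fraction:
        return Fraction(comb(n1, a) * comb(n2, K - a), denom)

    p_obs = prob(k1)
    gate = p_obs * (1 + Fraction(1, 10**7))
    total = Fraction(0)
    for a in range(max(0, K - n2), min(n1, K) + 1):
        p = prob(a)
        if p <= gate:
            total += p
    return float(min(total, Fraction(1)))


def motif_window_oracle(sequences, kmers, window):
    """Per-position fraction of sequences with >=1 k-mer start inside the
    width-`window` sliding window centered at each position."""
    L = len(sequences[0])
    left = window // 2
    right = window - left
    out = []
    for i in range(L):
        lo, hi = max(0, i - left), min(L, i + right)
        n_hit = 0
        for s in sequences:
            s = s.upper()
            if any(s.startswith(m, j) for j in range(lo, hi) for m in kmers):
                n_hit += 1
        out.append(n_hit / len(sequences))
    return out
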