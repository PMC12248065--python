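"""Motif scanning and positional motif architecture around PAS.

Per-nucleotide motif frequency maps use a sliding-window occurrence rule
(default 10 nt windows for 4-mers such as UGUA, 20 nt for 6-mers such as the
PAS hexamers) smoothed with a 5 nt running mean; G/C content profiles use a
10 nt running mean.  Spacing analyses measure the gap in nt between the 3'
end of the upstream motif and the 5' start of the downstream one (0 =
abutting).  All scanning is in the DNA alphabet; motifs are declared in RNA
and transliterated.  Minus-strand windows are reverse-complemented before
any scanning, so "upstream" is always transcript-5'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding_maps import PASAnchor, PositionalProfile
from .io_core import PeakSet, get_sense_sequence, reverse_complement


def rna_to_dna(kmer: str) -> str:
    return kmer.upper().replace("U", "T")


@dataclass
class MotifSpec:
    """A motif class: sense k-mers, their reverse complements, and the
    scanning window / smoothing span used for frequency maps."""

    name: str
    kmers: tuple[str, ...]  # RNA or DNA alphabet
    window: int = 10  # sliding-window width, nt
    smoothing: int = 5  # running-mean span, nt
    revcomp_kmers: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.kmers = tuple(rna_to_dna(k) for k in self.kmers)
        lengths = {len(k) for k in self.kmers}
        if len(lengths) != 1:
            raise ValueError("all k-mers in a MotifSpec must share one length")
        if self.window < self.k:
            raise ValueError("window must be >= k-mer length")
        if not self.revcomp_kmers:
            self.revcomp_kmers = tuple(reverse_complement(k) for k in self.kmers)
        else:
            self.revcomp_kmers = tuple(rna_to_dna(k) for k in self.revcomp_kmers)

    @property
    def k(self) -> int:
        return len(self.kmers[0])


UGUA = MotifSpec("UGUA", ("UGUA",), window=10, smoothing=5)
PAS_HEXAMER = MotifSpec("PAS_hexamer", ("AAUAAA", "AUUAAA"), window=20, smoothing=5)
AAUAAA = MotifSpec("AAUAAA", ("AAUAAA",), window=20, smoothing=5)


def running_mean(values: np.ndarray, span: int) -> np.ndarray:
    """Centered running mean, shrink-to-valid at the edges (length preserved).

    For even spans the window is [i - span//2, i + span - span//2).
    """
    if span <= 1:
        return np.asarray(values, dtype=float).copy()
    x = np.asarray(values, dtype=float)
    left = span // 2
    right = span - left  # window [i-left, i+right)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    lo = np.clip(np.arange(n) - left, 0, n)
    hi = np.clip(np.arange(n) + right, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def find_occurrences(seq: str, kmers: tuple[str, ...]) -> list[int]:
    """Sorted start indices of any of the k-mers in seq (overlaps included)."""
    hits: set[int] = set()
    for m in kmers:
        start = 0
        while True:
            j = seq.find(m, start)
            if j < 0:
                break
            hits.add(j)
            start = j + 1
    return sorted(hits)


def occurrence_matrix(sequences: list[str], kmers: tuple[str, ...]) -> np.ndarray:
    """Boolean (n_sequences x L) matrix: motif occurrence *starts* at column."""
    if not sequences:
        raise ValueError("no sequences supplied")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("all windows must have equal length")
    occ = np.zeros((len(sequences), L), dtype=bool)
    for i, s in enumerate(sequences):
        occ[i, find_occurrences(s.upper(), kmers)] = True
    return occ


def motif_frequency_map(sequences: list[str], motif: MotifSpec,
                        smooth: bool = True) -> PositionalProfile:
    """Per-position motif frequency across anchor-centered windows.

    ``values[i]`` is the fraction of sequences with >=1 occurrence *starting*
    within the ``motif.window``-nt sliding window centered at i (window
    [i - w//2, i + w - w//2)), then smoothed with the spec's running mean.
    Sequences must be equal-length, sense-orientation, anchor-centered
    (odd length; the anchor sits at the middle position).
    """
    occ = occurrence_matrix(sequences, motif.kmers)
    L = occ.shape[1]
    if L % 2 != 1:
        raise ValueError("windows must have odd length (centered anchor)")
    w = motif.window
    left = w // 2
    right = w - left
    csum = np.concatenate(
        (np.zeros((occ.shape[0], 1)), np.cumsum(occ, axis=1)), axis=1)
    lo = np.clip(np.arange(L) - left, 0, L)
    hi = np.clip(np.arange(L) + right, 0, L)
    any_occ = (csum[:, hi] - csum[:, lo]) > 0
    values = any_occ.mean(axis=0)
    if smooth:
        values = running_mean(values, motif.smoothing)
    half = L // 2
    return PositionalProfile("pas", (half, half), values, occ.shape[0])


def gc_profile(sequences: list[str], span: int = 10,
               smooth: bool = True) -> PositionalProfile:
    """Per-position G+C fraction across windows (running mean of 10 nt)."""
    if not sequences:
        raise ValueError("no sequences supplied")
    L = len(sequences[0])
    if L % 2 != 1 or any(len(s) != L for s in sequences):
        raise ValueError("windows must be equal odd length")
    arr = np.frombuffer("".join(s.upper() for s in sequences).encode(),
                        dtype="S1").reshape(len(sequences), L)
    values = ((arr == b"G") | (arr == b"C")).mean(axis=0)
    if smooth:
        values = running_mean(values, span)
    half = L // 2
    return PositionalProfile("pas", (half, half), values, len(sequences))


# ---------------------------------------------------------------------------
# spacing analyses

@dataclass
class SpacingDistribution:
    """Per-anchor minimum distances between two motif classes.

    ``distances`` holds the end-to-start gap in nt for each anchor with a
    valid pair; anchors lacking one are censored and only counted.
    """

    anchor_set_id: str
    distances: np.ndarray
    n_censored: int
    censoring_bound: int

    def __post_init__(self) -> None:
        d = self.distances
        if d.size and (d.min() < 0 or d.max() > self.censoring_bound):
            raise ValueError("distances must lie in [0, censoring_bound]")

    @property
    def n(self) -> int:
        return self.distances.size

    def cdf(self, grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF over distances; returns (grid, fraction <= grid)."""
        if grid is None:
            grid = np.arange(self.censoring_bound + 1)
        if self.distances.size == 0:
            return grid, np.zeros_like(grid, dtype=float)
        frac = np.searchsorted(np.sort(self.distances), grid, side="right") / self.n
        return grid, frac


def extract_anchor_windows(genome: dict[str, str], anchors: list[PASAnchor],
                           search: int) -> list[str]:
    """Sense-orientation windows of 2*search+1 nt centered on each anchor,
    N-padded at contig edges so every window has equal length."""
    out = []
    for a in anchors:
        lo, hi = a.position - search, a.position + search + 1
        seq = get_sense_sequence(genome, a.chrom, max(0, lo),
                                 min(len(genome[a.chrom]), hi), a.strand)
        pad_lo = max(0, -lo)
        pad_hi = max(0, hi - len(genome[a.chrom]))
        if a.strand == "+":
            seq = "N" * pad_lo + seq + "N" * pad_hi
        else:
            seq = "N" * pad_hi + seq + "N" * pad_lo
        out.append(seq)
    return out


def _min_gap_pair(up_starts: list[int], k_up: int,
                  down_starts: list[int], k_down: int,
                  anchor_index: int, max_gap: int) -> int | None:
    """Smallest end-to-start gap over pairs with the first motif strictly
    upstream; ties broken toward the pair whose downstream motif is closest
    to the anchor."""
    best: tuple[int, int] | None = None  # (gap, |down - anchor|)
    for a in up_starts:
        a_end = a + k_up
        for b in down_starts:
            if b < a_end:
                continue
            gap = b - a_end
            if gap > max_gap:
                continue
            key = (gap, abs(b - anchor_index))
            if best is None or key < best:
                best = key
    return best[0] if best else None


def anchors_with_proximal_peaks(anchors: list[PASAnchor], peaks: PeakSet,
                                proximal: int = 100) -> list[PASAnchor]:
    """Anchors with >=1 same-strand peak whose center lies within `proximal` nt."""
    centers: dict[tuple, np.ndarray] = {}
    for p in peaks.peaks:
        key = (p.interval.chrom, p.interval.strand)
        centers.setdefault(key, []).append(p.center)
    centers = {k: np.asarray(v) for k, v in centers.items()}
    kept = []
    for a in anchors:
        c = centers.get((a.chrom, a.strand))
        if c is not None and np.any(np.abs(c - a.position) <= proximal):
            kept.append(a)
    return kept


def motif_spacing_cdf(anchors: list[PASAnchor], genome: dict[str, str],
                      motif_a: MotifSpec = UGUA,
                      motif_b: MotifSpec = PAS_HEXAMER,
                      peaks: PeakSet | None = None,
                      search: int = 150, proximal: int = 100,
                      anchor_set_id: str = "") -> SpacingDistribution:
    """Distance between an upstream enhancer motif and the PAS hexamer.

    Anchors are first restricted to those with proximal binding (a peak
    center within ``proximal`` nt) when peaks are given.  Per anchor, the
    minimum gap between a ``motif_a`` occurrence strictly upstream of a
    ``motif_b`` occurrence is measured within +/- ``search`` nt; anchors
    lacking such a pair are censored.
    """
    if peaks is not None:
        anchors = anchors_with_proximal_peaks(anchors, peaks, proximal)
    windows = extract_anchor_windows(genome, anchors, search)
    dists = []
    censored = 0
    for seq in windows:
        a_starts = find_occurrences(seq, motif_a.kmers)
        b_starts = find_occurrences(seq, motif_b.kmers)
        gap = _min_gap_pair(a_starts, motif_a.k, b_starts, motif_b.k,
                            anchor_index=search, max_gap=search)
        if gap is None:
            censored += 1
        else:
            dists.append(gap)
    return SpacingDistribution(anchor_set_id, np.asarray(dists, dtype=int),
                               censored, search)


def revcomp_proximity(anchors: list[PASAnchor], genome: dict[str, str],
                      motif: MotifSpec, search: int,
                      anchor_set_id: str = "",
                      ) -> tuple[SpacingDistribution, dict[str, PositionalProfile]]:
    """Proximity of a motif to its own reverse complement around anchors.

    Per anchor: the minimum end-to-start gap between a sense occurrence and a
    reverse-complement occurrence (either order) within +/- ``search`` nt;
    anchors lacking either motif are censored.  Also returns per-position
    frequency maps of the sense and reverse-complement motifs.
    """
    windows = extract_anchor_windows(genome, anchors, search)
    dists = []
    censored = 0
    k = motif.k
    for seq in windows:
        sense = find_occurrences(seq, motif.kmers)
        rc = find_occurrences(seq, motif.revcomp_kmers)
        g1 = _min_gap_pair(sense, k, rc, k, search, search)
        g2 = _min_gap_pair(rc, k, sense, k, search, search)
        gaps = [g for g in (g1, g2) if g is not None]
        if not gaps:
            censored += 1
        else:
            dists.append(min(gaps))
    spacing = SpacingDistribution(anchor_set_id, np.asarray(dists, dtype=int),
                                  censored, search)
    rc_spec = MotifSpec(motif.name + "_rc", motif.revcomp_kmers,
                        motif.window, motif.smoothing)
    profiles = {
        "sense": motif_frequency_map(windows, motif),
        "revcomp": motif_frequency_map(windows, rc_spec),
    }
    return spacing, profiles
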