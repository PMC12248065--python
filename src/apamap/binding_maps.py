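"""eCLIP positional analytics around polyadenylation sites.

Four related views of where an RBP binds relative to 3' ends:

* the fraction of *expressed* 3'UTRs (median TPM >= 1 across controls) with
  any binding evidence;
* the distribution of reproducible peaks over transcript feature classes;
* per-nucleotide RNA maps — the fraction of anchor PAS with a peak covering
  each position of a window (default +/-500 nt, transcript orientation);
* per-position two-tailed Fisher exact enrichment of binding at regulated
  versus control PAS, reported as signed -log10 p.

"Bound at position i" means a same-strand peak interval covers that single
nucleotide.  No multiple-testing correction is applied across positions
(the enrichment heat maps plot raw -log10 p); Benjamini-Hochberg is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    FEATURE_PRIORITY,
    GeneModel,
    GenomicInterval,
    PeakSet,
    intersect_peaks,
    merge_intervals,
)


@dataclass
class PositionalProfile:
    """Per-nucleotide values in a window anchored on PAS or peak centers.

    ``values[i]`` corresponds to relative position ``positions[i]``
    (negative = upstream of the anchor in transcript orientation).
    """

    anchor: str  # "pas" or "peak_center"
    window: tuple[int, int]  # (upstream_nt, downstream_nt)
    values: np.ndarray
    n_anchors: int

    def __post_init__(self) -> None:
        up, down = self.window
        if self.values.shape[0] != up + down + 1:
            raise ValueError("profile length must be upstream + downstream + 1")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.window[0], self.window[1] + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "value": self.values,
                             "n": self.n_anchors})


@dataclass
class PASAnchor:
    """A single-nucleotide PAS anchor with optional read support."""

    chrom: str
    position: int
    strand: str
    reads: float = np.inf  # inf = expression filter not applicable


# ---------------------------------------------------------------------------

def expressed_utrs(genes: list[GeneModel], tpm: pd.DataFrame,
                   threshold: float = 1.0) -> list[GenomicInterval]:
    """3'UTR intervals of genes whose median control TPM meets the threshold.

    ``tpm`` needs a gene_id column; every other numeric column is treated as
    a control replicate.
    """
    value_cols = [c for c in tpm.columns if c != "gene_id"]
    med = tpm.set_index("gene_id")[value_cols].median(axis=1)
    keep = set(med[med >= threshold].index)
    return [utr for g in genes if g.gene_id in keep
            for utr in g.features.get("three_prime_utr", [])]


def binding_fraction_3utr(peaks: PeakSet,
                          utrs: list[GenomicInterval]) -> float:
    """Fraction of expressed 3'UTRs overlapped by >=1 same-strand peak."""
    if not utrs:
        raise ValueError("no expressed 3'UTRs supplied")
    bound, _ = intersect_peaks(peaks, utrs)
    return float(bound.mean())


def peak_feature_fractions(peaks: PeakSet, genes: list[GeneModel],
                           priority: tuple[str, ...] = FEATURE_PRIORITY,
                           ) -> pd.Series:
    """Assign each peak to exactly one feature class; return class fractions.

    A peak overlapping several classes takes the highest-priority one
    (default: 3'UTR > 5'UTR > CDS > non-coding exon > intron > downstream
    flank); peaks overlapping none fall in "other".  Fractions sum to 1.
    """
    features: list[GenomicInterval] = []
    labels: list[str] = []
    for g in genes:
        for cls in priority:
            for iv in g.features.get(cls, []):
                features.append(iv)
                labels.append(cls)
    _, assignment = intersect_peaks(peaks, features)
    rank = {cls: i for i, cls in enumerate(priority)}
    counts = {cls: 0 for cls in priority}
    counts["other"] = 0
    for hits in assignment:
        if hits:
            counts[min((labels[j] for j in hits), key=rank.__getitem__)] += 1
        else:
            counts["other"] += 1
    total = max(1, len(assignment))
    return pd.Series({k: v / total for k, v in counts.items()})


# ---------------------------------------------------------------------------
# RNA maps and positional Fisher enrichment

def _anchor_cover_matrix(peaks: PeakSet, anchors: list[PASAnchor],
                         window: tuple[int, int]) -> np.ndarray:
    """Boolean (n_anchors x window-length) matrix: peak covers position."""
    up, down = window
    width = up + down + 1
    cover = np.zeros((len(anchors), width), dtype=bool)
    by_key: dict[tuple, list[GenomicInterval]] = {}
    for p in peaks.intervals():
        by_key.setdefault((p.chrom, p.strand), []).append(p)
    for ai, a in enumerate(anchors):
        sign = 1 if a.strand == "+" else -1
        win_lo = a.position - (up if sign == 1 else down)
        win_hi = a.position + (down if sign == 1 else up)
        for p in by_key.get((a.chrom, a.strand), []):
            lo = max(p.start, win_lo)
            hi = min(p.end - 1, win_hi)
            if lo > hi:
                continue
            rel_a = sign * (lo - a.position)
            rel_b = sign * (hi - a.position)
            i0, i1 = sorted((rel_a + up, rel_b + up))
            cover[ai, i0:i1 + 1] = True
    return cover


def filter_anchors(anchors: list[PASAnchor],
                   min_anchor_reads: float = 100) -> list[PASAnchor]:
    """Keep highly expressed PAS (read support >= threshold)."""
    return [a for a in anchors if a.reads >= min_anchor_reads]


def rna_map(peaks: PeakSet, anchors: list[PASAnchor],
            window: tuple[int, int] = (500, 500),
            min_anchor_reads: float = 100) -> PositionalProfile:
    """Fraction of anchors with a same-strand peak covering each relative
    position; orientation is flipped for minus-strand anchors."""
    kept = filter_anchors(anchors, min_anchor_reads)
    if not kept:
        raise ValueError("no anchors pass the read-support filter")
    cover = _anchor_cover_matrix(peaks, kept, window)
    return PositionalProfile("pas", window, cover.mean(axis=0), len(kept))


@dataclass
class EnrichmentHeatRow:
    """Signed per-position -log10 p of binding enrichment at regulated vs
    control PAS, plus the 2x2 counts behind each position."""

    rbp_id: str
    window: tuple[int, int]
    signed_neglog10_p: np.ndarray
    p_values: np.ndarray
    bound_regulated: np.ndarray
    bound_control: np.ndarray
    n_regulated: int
    n_control: int
    cell_context: str = ""

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.window[0], self.window[1] + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "signed_neglog10_p": self.signed_neglog10_p,
            "p": self.p_values,
            "bound_regulated": self.bound_regulated,
            "bound_control": self.bound_control,
            "n_regulated": self.n_regulated,
            "n_control": self.n_control,
        })


def fisher_two_tailed(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-tailed Fisher exact p for bound counts k1/n1 vs k2/n2.

    Standard exact two-tail: the sum of probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    Positions with zero bound in both sets give p = 1.
    """
    if k1 == 0 and k2 == 0:
        return 1.0
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def positional_fisher(peaks: PeakSet, regulated: list[PASAnchor],
                      control: list[PASAnchor],
                      window: tuple[int, int] = (500, 500),
                      rbp_id: str = "", cell_context: str = "",
                      bh_correct: bool = False) -> EnrichmentHeatRow:
    """Per-position two-tailed Fisher exact test of binding enrichment.

    At each relative position the 2x2 table is [bound, unbound] x
    [regulated, control]; the sign is positive where the regulated
    bound-fraction exceeds the control one.
    """
    if not regulated or not control:
        raise ValueError("regulated and control anchor sets must be non-empty")
    overlap = {(a.chrom, a.position, a.strand) for a in regulated} & {
        (a.chrom, a.position, a.strand) for a in control}
    if overlap:
        raise ValueError(f"regulated and control sets share {len(overlap)} anchors")
    cov_r = _anchor_cover_matrix(peaks, regulated, window)
    cov_c = _anchor_cover_matrix(peaks, control, window)
    k_r = cov_r.sum(axis=0)
    k_c = cov_c.sum(axis=0)
    n_r, n_c = len(regulated), len(control)
    pvals = np.array([fisher_two_tailed(int(a), n_r, int(b), n_c)
                      for a, b in zip(k_r, k_c)])
    if bh_correct:
        pvals = _benjamini_hochberg(pvals)
    sign = np.sign(k_r / n_r - k_c / n_c)
    sign[sign == 0] = 1.0
    signed = sign * -np.log10(np.clip(pvals, 1e-300, 1.0))
    return EnrichmentHeatRow(rbp_id, window, signed, pvals, k_r, k_c,
                             n_r, n_c, cell_context)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ---------------------------------------------------------------------------

def jaccard_overlap(peaks_a: PeakSet, peaks_b: PeakSet) -> float:
    """Base-pair Jaccard index between two peak sets.

    Intervals are merged per (chrom, strand) first; the index is
    |intersection bp| / |union bp| (0 when both sets are empty).
    """
    a = merge_intervals(peaks_a.intervals())
    b = merge_intervals(peaks_b.intervals())
    bp_a = sum(len(iv) for iv in a)
    bp_b = sum(len(iv) for iv in b)
    inter = 0
    by_key: dict[tuple, list[GenomicInterval]] = {}
    for iv in b:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for iv in a:
        for jv in by_key.get((iv.chrom, iv.strand), []):
            inter += max(0, min(iv.end, jv.end) - max(iv.start, jv.start))
    union = bp_a + bp_b - inter
    return inter / union if union else 0.0


def jaccard_matrix(peaksets: list[PeakSet]) -> pd.DataFrame:
    ids = [ps.experiment_id for ps in peaksets]
    m = np.eye(len(peaksets))
    for i in range(len(peaksets)):
        for j in range(i + 1, len(peaksets)):
            m[i, j] = m[j, i] = jaccard_overlap(peaksets[i], peaksets[j])
    return pd.DataFrame(m, index=ids, columns=ids)
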