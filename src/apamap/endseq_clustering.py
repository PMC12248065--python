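"""3'-end read cluster calling, PAS assignment and internal-priming filters.

Cleavage/polyadenylation is imprecise, so single-nucleotide read 3' ends are
merged into clusters before quantification: coverage is pooled across *all*
samples in the run, and a cluster is a maximal run of positions whose pooled
coverage is strictly greater than ``min_per_base`` (default 10, i.e. >=11
reads); clusters totalling fewer than ``min_cluster_reads`` (default 20)
pooled reads are discarded.  One single-nucleotide PAS is then assigned per
cluster (coverage argmax, ties broken toward the transcript 3' end).

Oligo-dT library preparations misprime on genomically encoded A-rich runs,
producing false 3' ends.  Four filters guard against this and against
spurious sites:

* ``a_run``     — >6 consecutive genomic adenosines (sense strand) directly
                  downstream of the assigned PAS;
* ``a_content`` — >7 adenosines within the 10 nt directly downstream of the
                  cluster's 3' boundary;
* ``hexamer``   — cluster must contain one of the top two PAS hexamers
                  (AAUAAA/AUUAAA); the search window may be extended a
                  configurable margin upstream of the cluster (default 25 nt)
                  because the hexamer canonically sits 10-20 nt upstream of
                  the cleavage site and narrow clusters would otherwise never
                  contain it;
* ``reference`` — cluster must overlap a reference PAS database record on the
                  same strand.

A surviving cluster has all four flags False.  The filters are independent
and may be applied in any order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenomicInterval, get_sense_sequence

FILTER_NAMES = ("a_run_fail", "a_content_fail", "hexamer_fail", "reference_fail")
HEXAMERS_DNA = ("AATAAA", "ATTAAA")


@dataclass
class EndCluster:
    """A contiguous 3'-end read cluster with its assigned PAS and filter flags."""

    interval: GenomicInterval
    coverage: np.ndarray  # pooled per-base coverage over the interval
    counts: dict[str, int]  # per-sample read counts within the interval
    total_reads: int
    pas_position: int = -1
    filter_flags: dict[str, bool] = field(
        default_factory=lambda: {k: False for k in FILTER_NAMES})
    hexamer_found: str = "none"

    def __post_init__(self) -> None:
        if self.total_reads != int(np.sum(self.coverage)):
            raise ValueError("total_reads must equal summed pooled coverage")

    @property
    def survives(self) -> bool:
        return not any(self.filter_flags.values())


def call_clusters(per_sample_ends: dict[str, pd.DataFrame],
                  min_per_base: int = 10,
                  min_cluster_reads: int = 20) -> list[EndCluster]:
    """Call clusters from per-sample 3'-end positions, pooled across samples.

    ``per_sample_ends`` maps sample id to a DataFrame with columns
    (chrom, pos, strand), one row per read 3' end.  Clustering is done per
    (chrom, strand).  Returns clusters sorted by (chrom, strand, start) with
    PAS already assigned.
    """
    if not per_sample_ends:
        return []
    pooled = pd.concat(
        [df.assign(sample=sid) for sid, df in per_sample_ends.items()],
        ignore_index=True)
    if pooled.empty:
        return []
    clusters: list[EndCluster] = []
    for (chrom, strand), grp in pooled.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        lo, hi = int(pos.min()), int(pos.max())
        cov = np.bincount(pos - lo, minlength=hi - lo + 1)
        for s, e in _coverage_runs(cov, min_per_base):
            total = int(cov[s:e].sum())
            if total < min_cluster_reads:
                continue
            iv = GenomicInterval(chrom, lo + s, lo + e, strand)
            in_iv = (pos >= iv.start) & (pos < iv.end)
            counts = (grp.loc[in_iv, "sample"].value_counts()
                      .reindex(per_sample_ends.keys(), fill_value=0).to_dict())
            cl = EndCluster(iv, cov[s:e].copy(), counts, total)
            cl.pas_position = assign_pas(cl)
            clusters.append(cl)
    return clusters


def _coverage_runs(cov: np.ndarray, min_per_base: int):
    """Maximal runs of positions with coverage strictly > min_per_base."""
    above = cov > min_per_base
    if not above.any():
        return
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))
                                   .astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e)


def assign_pas(cluster: EndCluster) -> int:
    """Single-nucleotide PAS: pooled-coverage argmax, ties to the 3'-most position.

    "3'-most" is transcript-orientation: the highest coordinate on +, the
    lowest on -.
    """
    cov = cluster.coverage
    if cov.size == 0:
        raise ValueError("empty cluster")
    best = np.flatnonzero(cov == cov.max())
    off = int(best.max()) if cluster.interval.strand == "+" else int(best.min())
    return cluster.interval.start + off


# ---------------------------------------------------------------------------
# filters

def _downstream_window(genome, chrom: str, pos_after: int, strand: str,
                       window: int) -> str:
    """Sense-strand sequence of `window` nt starting at the position directly
    3' (transcript orientation) of coordinate boundary ``pos_after``."""
    if strand == "+":
        return get_sense_sequence(genome, chrom, pos_after, pos_after + window, "+")
    return get_sense_sequence(genome, chrom, pos_after - window, pos_after, "-")


def _longest_a_run(seq: str) -> int:
    best = run = 0
    for ch in seq:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    return best


def filter_a_run(cluster: EndCluster, genome, max_run: int = 6,
                 window: int = 10) -> bool:
    """Flag clusters with > max_run consecutive sense-strand A directly
    downstream of the PAS (inspected over `window` nt)."""
    iv = cluster.interval
    if iv.strand == "+":
        seq = _downstream_window(genome, iv.chrom, cluster.pas_position + 1,
                                 "+", window)
    else:
        seq = _downstream_window(genome, iv.chrom, cluster.pas_position,
                                 "-", window)
    flag = _longest_a_run(seq) > max_run
    cluster.filter_flags["a_run_fail"] = flag
    return flag


def filter_a_content(cluster: EndCluster, genome, window: int = 10,
                     max_a: int = 7) -> bool:
    """Flag clusters with > max_a sense-strand A in the `window` nt directly
    downstream of the cluster's 3' boundary."""
    iv = cluster.interval
    boundary = iv.end if iv.strand == "+" else iv.start
    seq = _downstream_window(genome, iv.chrom, boundary, iv.strand, window)
    flag = seq.count("A") > max_a
    cluster.filter_flags["a_content_fail"] = flag
    return flag


def filter_hexamer(cluster: EndCluster, genome,
                   upstream_margin: int = 25) -> bool:
    """Require one of the top two PAS hexamers within the cluster sequence.

    The sense-strand search window is the cluster interval extended
    ``upstream_margin`` nt upstream (transcript orientation); with margin 0
    this is strict containment.  Records which hexamer was found (RNA
    alphabet); AAUAAA is preferred when both occur.
    """
    iv = cluster.interval
    if iv.strand == "+":
        seq = get_sense_sequence(genome, iv.chrom, iv.start - upstream_margin,
                                 iv.end, "+")
    else:
        seq = get_sense_sequence(genome, iv.chrom, iv.start,
                                 iv.end + upstream_margin, "-")
    found = "none"
    for hx in HEXAMERS_DNA:
        if hx in seq:
            found = hx.replace("T", "U")
            break
    cluster.hexamer_found = found
    flag = found == "none"
    cluster.filter_flags["hexamer_fail"] = flag
    return flag


def filter_reference(clusters: list[EndCluster],
                     reference_pas: list[tuple[GenomicInterval, str, float]] | list[GenomicInterval],
                     ) -> list[bool]:
    """Flag clusters that overlap no same-strand reference PAS record."""
    refs = [r[0] if isinstance(r, tuple) else r for r in reference_pas]
    if not refs:
        warnings.warn("empty reference PAS set: all clusters flagged")
    flags = []
    by_key: dict[tuple, list[GenomicInterval]] = {}
    for r in refs:
        by_key.setdefault((r.chrom, r.strand), []).append(r)
    for cl in clusters:
        iv = cl.interval
        hit = any(iv.start < r.end and r.start < iv.end
                  for r in by_key.get((iv.chrom, iv.strand), []))
        cl.filter_flags["reference_fail"] = not hit
        flags.append(not hit)
    return flags


def apply_filters(clusters: list[EndCluster], genome,
                  reference_pas=None,
                  a_run_max: int = 6, a_run_window: int = 10,
                  a_content_window: int = 10, a_content_max: int = 7,
                  hexamer_upstream_margin: int = 25) -> list[EndCluster]:
    """Run the full filter battery in place; returns the surviving clusters."""
    for cl in clusters:
        filter_a_run(cl, genome, a_run_max, a_run_window)
        filter_a_content(cl, genome, a_content_window, a_content_max)
        filter_hexamer(cl, genome, hexamer_upstream_margin)
    if reference_pas is not None:
        filter_reference(clusters, reference_pas)
    return [cl for cl in clusters if cl.survives]


def clusters_table(clusters: list[EndCluster]) -> pd.DataFrame:
    """Flat per-cluster table (interval, PAS, flags, per-sample counts)."""
    rows = []
    for i, cl in enumerate(clusters):
        row = {
            "cluster_id": f"c{i:05d}",
            "chrom": cl.interval.chrom, "start": cl.interval.start,
            "end": cl.interval.end, "strand": cl.interval.strand,
            "pas_position": cl.pas_position, "total_reads": cl.total_reads,
            "hexamer": cl.hexamer_found, "survives": cl.survives,
        }
        row.update(cl.filter_flags)
        row.update({f"reads_{s}": c for s, c in cl.counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)
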