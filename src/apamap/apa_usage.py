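"""Per-terminal-exon PAS usage and replicate-consistent differential calls.

Relative usage of each surviving cluster is its read count over the summed
reads of all clusters in the same terminal exon, per sample.  A PAS cluster
is called *changing* between knockdown and control when at least 2 of 3
matched replicate pairs shift by >=10% usage in the same direction and no
pair shifts in the opposite direction (the rule generalises to ceil(2k/3) of
k pairs).  A terminal exon is *confidently non-changing* when it has >=10
reads in every sample and no cluster moves more than 5% in any replicate.
Compartment-specific events are exons changing in one compartment and
confidently non-changing in the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .endseq_clustering import EndCluster
from .io_core import GeneModel


@dataclass
class TerminalExonUsage:
    """Usage of each surviving PAS cluster within one terminal exon.

    ``usage`` is samples x clusters (fractions summing to 1 per sample with
    reads; NaN for zero-read samples); clusters are ordered 5'->3' in
    transcript orientation.  ``deltas`` (replicate x cluster, KD - control)
    and call fields are filled by :func:`call_changes`.
    """

    exon_id: str
    strand: str
    clusters: list[EndCluster]
    counts: pd.DataFrame  # samples x clusters, raw reads
    usage: pd.DataFrame  # samples x clusters, fractions (NaN when total==0)
    deltas: pd.DataFrame | None = None
    call: str = "uncalled"  # changing | non_changing | indeterminate | uncalled
    cluster_direction: dict[int, str] = field(default_factory=dict)  # {idx: up|down}
    exon_direction: str = "none"  # lengthening | shortening | none

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def assign_clusters_to_exons(clusters: list[EndCluster],
                             genes: list[GeneModel],
                             flank: int = 0) -> dict[str, list[EndCluster]]:
    """Map each cluster to the terminal exon containing its PAS.

    The exon may be extended ``flank`` nt past its 3' end because 3'-end-seq
    clusters can run past annotated ends.  A cluster is assigned to at most
    one exon (first containing exon wins; synthetic and real terminal exons
    do not overlap on the same strand).
    """
    out: dict[str, list[EndCluster]] = {}
    exons = []
    for g in genes:
        te = g.terminal_exon
        if te is None:
            continue
        lo, hi = te.start, te.end
        if flank > 0:
            if g.strand == "+":
                hi += flank
            else:
                lo = max(0, lo - flank)
        exons.append((g.gene_id + "_te", g.chrom, g.strand, lo, hi))
    for cl in clusters:
        iv = cl.interval
        for eid, chrom, strand, lo, hi in exons:
            if (chrom, strand) == (iv.chrom, iv.strand) and lo <= cl.pas_position < hi:
                out.setdefault(eid, []).append(cl)
                break
    return out


def compute_usage(clusters: list[EndCluster], genes: list[GeneModel],
                  flank: int = 0) -> dict[str, TerminalExonUsage]:
    """Per-exon relative usage of each cluster in each sample."""
    by_exon = assign_clusters_to_exons(clusters, genes, flank)
    strands = {g.gene_id + "_te": g.strand for g in genes}
    out: dict[str, TerminalExonUsage] = {}
    for eid, cls in by_exon.items():
        strand = strands[eid]
        # order clusters 5'->3' in transcript orientation
        cls = sorted(cls, key=lambda c: c.pas_position, reverse=(strand == "-"))
        counts = pd.DataFrame({i: pd.Series(c.counts) for i, c in enumerate(cls)})
        totals = counts.sum(axis=1)
        usage = counts.div(totals, axis=0)  # zero-read samples become NaN
        out[eid] = TerminalExonUsage(eid, strand, cls, counts, usage)
    return out


def _replicate_pairs(manifest: pd.DataFrame, compartment: str | None,
                     conditions: tuple[str, str]) -> list[tuple[str, str, int]]:
    """Matched (control_sample, kd_sample, replicate) tuples."""
    m = manifest
    if compartment is not None:
        m = m[m["compartment"] == compartment]
    ctrl, kd = conditions
    pairs = []
    for rep, grp in m.groupby("replicate"):
        c = grp[grp["condition"] == ctrl]["sample"]
        k = grp[grp["condition"] == kd]["sample"]
        if len(c) == 1 and len(k) == 1:
            pairs.append((c.iloc[0], k.iloc[0], int(rep)))
        else:
            # a replicate lacking its matched pair invalidates the design
            return []
    return pairs


def call_changes(exon: TerminalExonUsage, manifest: pd.DataFrame,
                 min_delta: float = 0.10,
                 compartment: str | None = None,
                 conditions: tuple[str, str] = ("control", "kd"),
                 ) -> TerminalExonUsage:
    """Differential call for one exon under the replicate-consistency rule.

    Per matched replicate pair, delta = KD usage - control usage per cluster.
    A cluster is changing iff >= ceil(2k/3) of the k pairs have
    |delta| >= min_delta with a common sign and *no* pair has the opposite
    sign at any magnitude (exact zeros are neutral).  The exon is changing
    iff any cluster is; exons with a single cluster, or with a missing or
    unusable replicate pair, are indeterminate.
    """
    pairs = _replicate_pairs(manifest, compartment, conditions)
    exon.deltas = None
    exon.call = "indeterminate"
    exon.cluster_direction = {}
    exon.exon_direction = "none"
    if len(exon.clusters) < 2 or not pairs:
        return exon
    missing = [s for c, k, _ in pairs for s in (c, k) if s not in exon.usage.index]
    if missing:
        return exon
    deltas = pd.DataFrame(
        {rep: exon.usage.loc[k] - exon.usage.loc[c] for c, k, rep in pairs}
    ).T  # replicates x clusters
    if deltas.isna().any().any():
        return exon
    exon.deltas = deltas
    need = math.ceil(2 * len(pairs) / 3)
    changing = False
    for ci in deltas.columns:
        d = deltas[ci].to_numpy()
        for sign in (1, -1):
            if (np.sum(sign * d >= min_delta) >= need) and not np.any(sign * d < 0):
                exon.cluster_direction[ci] = "up" if sign > 0 else "down"
                changing = True
                break
    exon.call = "changing" if changing else "not_changing"
    if changing:
        distal = deltas.columns[-1]
        d_distal = float(deltas[distal].mean())
        exon.exon_direction = "shortening" if d_distal < 0 else "lengthening"
    return exon


def call_nonchanging(exon: TerminalExonUsage, manifest: pd.DataFrame,
                     min_reads: int = 10, max_delta: float = 0.05,
                     compartment: str | None = None,
                     conditions: tuple[str, str] = ("control", "kd"),
                     ) -> bool:
    """Confident non-changing: >=min_reads total in *every* sample and no
    cluster moving more than max_delta in any replicate pair."""
    pairs = _replicate_pairs(manifest, compartment, conditions)
    if not pairs:
        return False
    samples = [s for c, k, _ in pairs for s in (c, k)]
    if any(s not in exon.counts.index for s in samples):
        return False
    if (exon.totals.loc[samples] < min_reads).any():
        return False
    deltas = pd.DataFrame(
        {rep: exon.usage.loc[k] - exon.usage.loc[c] for c, k, rep in pairs}).T
    if deltas.isna().any().any():
        return False
    ok = bool((deltas.abs() <= max_delta).all().all())
    if ok and exon.call in ("uncalled", "not_changing", "indeterminate"):
        exon.call = "non_changing"
    return ok


def call_all(exons: dict[str, TerminalExonUsage], manifest: pd.DataFrame,
             compartment: str | None = None,
             min_delta: float = 0.10, min_reads: int = 10,
             max_delta_null: float = 0.05,
             conditions: tuple[str, str] = ("control", "kd"),
             ) -> pd.DataFrame:
    """Run changing + confident-non-changing calls over all exons.

    Returns a per-exon table with columns (exon_id, call, direction);
    ``call`` is one of changing / non_changing / indeterminate (exons
    passing neither rule are indeterminate for compartment logic).
    """
    rows = []
    for eid, exon in exons.items():
        call_changes(exon, manifest, min_delta, compartment, conditions)
        if exon.call == "changing":
            final = "changing"
        elif call_nonchanging(exon, manifest, min_reads, max_delta_null,
                              compartment, conditions):
            final = "non_changing"
        else:
            final = "indeterminate"
        rows.append({"exon_id": eid, "call": final,
                     "direction": exon.exon_direction})
    return pd.DataFrame(rows)


def compare_compartments(nuclear_calls: pd.DataFrame,
                         cytoplasmic_calls: pd.DataFrame,
                         ) -> dict[str, set[str]]:
    """Shared / compartment-specific changing terminal exons.

    Shared: changing in both.  Compartment-specific: changing in one AND
    confidently non-changing in the other.  Changing-vs-indeterminate pairs
    belong to no set.  The three sets are disjoint.
    """
    nuc = nuclear_calls.set_index("exon_id")["call"]
    cyt = cytoplasmic_calls.set_index("exon_id")["call"]
    ids = nuc.index.union(cyt.index)
    nuc = nuc.reindex(ids, fill_value="indeterminate")
    cyt = cyt.reindex(ids, fill_value="indeterminate")
    shared = set(ids[(nuc == "changing") & (cyt == "changing")])
    cyto_specific = set(ids[(cyt == "changing") & (nuc == "non_changing")])
    nuc_specific = set(ids[(nuc == "changing") & (cyt == "non_changing")])
    return {"shared": shared, "cytoplasm_specific": cyto_specific,
            "nucleus_specific": nuc_specific}


def usage_table(exons: dict[str, TerminalExonUsage]) -> pd.DataFrame:
    """Long-format per-exon, per-cluster, per-sample usage table."""
    rows = []
    for eid, exon in exons.items():
        for ci, cl in enumerate(exon.clusters):
            for sample in exon.usage.index:
                rows.append({
                    "exon_id": eid, "cluster_index": ci,
                    "pas_position": cl.pas_position, "sample": sample,
                    "reads": int(exon.counts.loc[sample, ci]),
                    "usage": float(exon.usage.loc[sample, ci]),
                })
    return pd.DataFrame(rows)
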