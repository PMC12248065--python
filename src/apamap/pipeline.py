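"""One-config end-to-end run over a synthetic scenario.

Chains every stage — simulate, cluster + filter, usage, differential calls
(and compartment overlap when two compartments are simulated), dPDUI
classification, RNA map, positional Fisher enrichment, motif spacing and GC
profile — and writes each declared TSV into the output directory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import (
    apa_usage,
    binding_maps,
    endseq_clustering,
    motif_maps,
    synthetic_data,
    tandem_apa,
)
from .io_core import write_bed6, write_fasta, write_gtf, write_narrowpeak
from .synthetic_data import SimConfig


def run_pipeline(config: SimConfig | str | Path, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the full synthetic pipeline; returns in-memory results keyed by stage."""
    if not isinstance(config, SimConfig):
        config = SimConfig.from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, rng_seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}

    # --- simulate -----------------------------------------------------------
    genome, genes, truth = synthetic_data.simulate_genome(config)
    samples = synthetic_data.default_samples(config)
    manifest = synthetic_data.make_manifest(samples)
    reads = synthetic_data.simulate_endseq(config, truth, samples)
    peaks = synthetic_data.simulate_peaks(config, truth)
    ref_pas = synthetic_data.reference_pas_records(truth)
    dpdui = synthetic_data.simulate_dpdui_table(config, truth)

    write_fasta(genome, out / "genome.fa")
    write_gtf(genes, out / "annotation.gtf")
    write_bed6(ref_pas, out / "reference_pas.bed", "reference PAS database")
    write_narrowpeak(peaks, out / "peaks.narrowPeak")
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    dpdui.to_csv(out / "dpdui_table.tsv", sep="\t", index=False)
    for sid, df in reads.items():
        synthetic_data.write_endseq_bed(df, out / f"ends_{sid}.bed")
    results.update(genome=genome, genes=genes, truth=truth, manifest=manifest,
                   reads=reads, peaks=peaks)

    # --- cluster + filter ---------------------------------------------------
    clusters = endseq_clustering.call_clusters(reads)
    surviving = endseq_clustering.apply_filters(clusters, genome, ref_pas)
    endseq_clustering.clusters_table(clusters).to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    results.update(clusters=clusters, surviving=surviving)

    # --- usage + differential calls -----------------------------------------
    exons = apa_usage.compute_usage(surviving, genes)
    apa_usage.usage_table(exons).to_csv(out / "usage.tsv", sep="\t", index=False)
    calls = {}
    for comp in config.compartments:
        comp_arg = None if comp == "whole" else comp
        calls[comp] = apa_usage.call_all(exons, manifest, compartment=comp_arg,
                                         conditions=config.conditions)
        calls[comp].to_csv(out / f"calls_{comp}.tsv", sep="\t", index=False)
    results["calls"] = calls
    if {"nuclear", "cytoplasmic"} <= set(config.compartments):
        overlap = apa_usage.compare_compartments(calls["nuclear"],
                                                 calls["cytoplasmic"])
        pd.DataFrame(
            [{"set": k, "exon_id": e} for k, v in overlap.items()
             for e in sorted(v)]
        ).to_csv(out / "compartment_overlap.tsv", sep="\t", index=False)
        results["compartments"] = overlap

    # --- dPDUI classification -----------------------------------------------
    dpdui_calls = tandem_apa.classify_calls(dpdui)
    dpdui_calls.to_csv(out / "dpdui_calls.tsv", sep="\t", index=False)
    pd.DataFrame([tandem_apa.summarize_rbp(dpdui_calls, rbp_id="simRBP")]).to_csv(
        out / "rbp_summary.tsv", sep="\t", index=False)
    results["dpdui_calls"] = dpdui_calls

    # --- binding maps -------------------------------------------------------
    anchors = [binding_maps.PASAnchor(c.interval.chrom, c.pas_position,
                                      c.interval.strand, c.total_reads)
               for c in surviving]
    profile = binding_maps.rna_map(peaks, anchors)
    profile.to_frame().to_csv(out / "rna_map.tsv", sep="\t", index=False)
    results["rna_map"] = profile

    comp0 = config.compartments[0]
    call_df = calls[comp0].set_index("exon_id")["call"]
    by_exon = {eid: exon for eid, exon in exons.items()}
    reg_anchors, ctl_anchors = [], []
    for eid, exon in by_exon.items():
        distal = exon.clusters[-1]
        a = binding_maps.PASAnchor(distal.interval.chrom, distal.pas_position,
                                   distal.interval.strand, distal.total_reads)
        if call_df.get(eid) == "changing":
            reg_anchors.append(a)
        elif call_df.get(eid) == "non_changing":
            ctl_anchors.append(a)
    if reg_anchors and ctl_anchors:
        heat = binding_maps.positional_fisher(peaks, reg_anchors, ctl_anchors,
                                              rbp_id="simRBP")
        heat.to_frame().to_csv(out / "fisher_map.tsv", sep="\t", index=False)
        results["fisher_map"] = heat

    # --- motif architecture -------------------------------------------------
    spacing = motif_maps.motif_spacing_cdf(anchors, genome, peaks=peaks)
    grid, frac = spacing.cdf()
    pd.DataFrame({"distance": grid, "cdf": frac}).to_csv(
        out / "spacing_cdf.tsv", sep="\t", index=False)
    pd.DataFrame({"anchor_index": range(spacing.n),
                  "distance": spacing.distances}).to_csv(
        out / "spacing.tsv", sep="\t", index=False)
    windows = motif_maps.extract_anchor_windows(genome, anchors, 150)
    gc = motif_maps.gc_profile(windows)
    gc.to_frame().to_csv(out / "gc_profile.tsv", sep="\t", index=False)
    results.update(spacing=spacing, gc_profile=gc)
    return results
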