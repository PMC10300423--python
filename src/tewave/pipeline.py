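"""End-to-end orchestration: simulate/ingest -> join -> annotate -> enrich.

The pipeline is driven by a single YAML/dict config.  All stochastic
steps derive their seeds from the config seed and are recorded in a
machine-readable run manifest together with SHA-256 checksums of every
output file, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import (GeneModel, SimulationConfig, aggregate_joined,
               associate_monomers, binary_metagene, cluster_enrichment,
               feature_peak_enrichment, filter_by_auc,
               filter_peaks_min_length, find_clusters, genes_in_clusters,
               group_vs_random_expression, join_line1_fragments,
               annotate_peak_categories, assign_peaks_to_te,
               results_to_frame, simulate_counts, simulate_genome_annotation,
               simulate_peaks_and_signal, stage_membership,
               tss_enrichment_test, tmm_normalize, write_bed, write_bedgraph,
               write_gtf_genes, write_narrowpeak, write_repeatmasker)

logger = logging.getLogger("tewave")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def run_pipeline(config: dict | str | Path, outdir) -> dict:
    """Run the full synthetic analysis; returns the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    sim_overrides = dict(config.get("simulate", {}))
    sim_overrides.setdefault("seed", seed)
    sim_config = SimulationConfig(**sim_overrides)
    n_perm = int(config.get("n_perm", 1000))

    manifest: dict = {"seed": seed, "n_perm": n_perm,
                      "simulate": dataclasses.asdict(sim_config),
                      "stages": list(sim_config.stages), "outputs": {}}

    def save(name, writer):
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    # --- simulate ------------------------------------------------------
    ann = simulate_genome_annotation(sim_config)
    peaks = simulate_peaks_and_signal(ann)
    counts = simulate_counts(ann)
    save("chrom.sizes", lambda p: Path(p).write_text("".join(
        f"{c}\t{ann.layout.length(c)}\n" for c in ann.layout.chrom_names)))
    save("genes.gtf", lambda p: write_gtf_genes(p, ann.genes))
    save("rmsk.tsv", lambda p: write_repeatmasker(p, ann.tes))
    save("monomers.bed", lambda p: write_bed(
        p, [m.locus for m in ann.monomers]))
    for stage in sim_config.stages:
        save(f"peaks_atac_{stage}.narrowPeak", lambda p, s=stage:
             write_narrowpeak(p, [(pk.locus, 0.0) for pk in peaks.atac[s]]))
        save(f"peaks_polii_{stage}.narrowPeak", lambda p, s=stage:
             write_narrowpeak(p, [(pk.locus, 0.0) for pk in peaks.polii[s]]))
        save(f"signal_polii_{stage}.bedGraph", lambda p, s=stage:
             write_bedgraph(p, peaks.polii_signal[s]))
    save("counts.tsv", lambda p: counts.counts.to_csv(p, sep="\t"))

    # --- LINE-1 joining and monomer association ------------------------
    joined, join_map = join_line1_fragments(
        [t for t in ann.tes if t.te_class == "LINE"])
    non_line = [t for t in ann.tes if t.te_class != "LINE"]
    te_joined = sorted(joined + non_line,
                       key=lambda t: (t.locus.chrom, t.locus.start))
    save("joined_l1.bed", lambda p: write_bed(
        p, [t.locus for t in joined]))
    save("join_map.tsv", lambda p: pd.Series(
        join_map, name="joined_id").rename_axis("source_id").to_csv(
        p, sep="\t"))
    monomers = associate_monomers(ann.monomers, joined)
    save("monomer_associations.tsv", lambda p: pd.DataFrame(
        [{"monomer": m.locus.name, "type": m.monomer_type,
          "line1": m.associated_line1} for m in monomers]).to_csv(
        p, sep="\t", index=False))

    # --- peak annotation per stage -------------------------------------
    model = GeneModel.build(ann.genes, ann.layout)
    stage_summary = {}
    intergenic_by_stage = {}
    for stage in sim_config.stages:
        stage_peaks = filter_peaks_min_length(peaks.atac[stage])
        annotated = annotate_peak_categories(stage_peaks, model)
        intergenic = [p for p in annotated if p.category == "intergenic"]
        assigned = assign_peaks_to_te(intergenic, te_joined)
        intergenic_by_stage[stage] = assigned
        cats = pd.Series([p.category for p in annotated]).value_counts()
        stage_summary[stage] = cats
        save(f"peak_annotation_{stage}.tsv", lambda p, ps=assigned:
             pd.DataFrame([{
                 "peak": x.locus.name, "chrom": x.locus.chrom,
                 "start": x.locus.start, "end": x.locus.end,
                 "category": x.category, "te_id": x.te_id,
                 "te_subfamily": x.te_subfamily} for x in ps]).to_csv(
             p, sep="\t", index=False))
    save("peak_category_counts.tsv", lambda p: pd.DataFrame(
        stage_summary).fillna(0).astype(int).to_csv(p, sep="\t"))

    # --- gene clusters and enrichment ----------------------------------
    clusters, singletons = find_clusters(ann.genes)
    save("clusters.bed", lambda p: write_bed(
        p, [c.locus for c in clusters]))
    focal = [g for g in ann.genes if g.gene_id in set(ann.truth.focal_genes)]
    n_in, _ids = genes_in_clusters(focal, clusters)
    enr = cluster_enrichment(focal, clusters, ann.layout,
                             n_perm=n_perm, seed=seed)
    save("cluster_enrichment.tsv", lambda p: results_to_frame(
        {"focal_vs_shuffled_clusters": enr}).to_csv(p, sep="\t"))
    manifest["cluster_genes_observed"] = n_in

    # --- TSS TE enrichment ---------------------------------------------
    tss_res = tss_enrichment_test(focal, ann.genes, ann.tes, ann.layout,
                                  n_perm=n_perm, seed=seed)
    save("tss_enrichment.tsv",
         lambda p: results_to_frame(tss_res).to_csv(p, sep="\t"))

    # --- Pol-II on monomers --------------------------------------------
    polii_filtered = {
        stage: filter_by_auc(peaks.polii[stage],
                             peaks.polii_signal[stage])
        for stage in sim_config.stages}
    mono_loci = [m.locus for m in monomers if m.associated_line1]
    polii_res = feature_peak_enrichment(
        mono_loci, polii_filtered, ann.layout, flank=100,
        n_perm=min(n_perm, 200), seed=seed)
    save("polii_monomer_enrichment.tsv",
         lambda p: results_to_frame(polii_res).to_csv(p, sep="\t"))
    late = sim_config.stages[-1]
    early = [s for s in ("early2C", "late2C")
             if s in polii_filtered and s != late]
    membership, pattern_counts, frac = stage_membership(
        mono_loci, polii_filtered, late_stage=late, early_stages=early)
    save("polii_stage_membership.tsv",
         lambda p: membership.to_csv(p, sep="\t"))
    save("polii_membership_patterns.tsv", lambda p: pattern_counts
         .rename("n_features").to_csv(p, sep="\t"))
    manifest["eightC_bound_earlier_fraction"] = frac

    # --- metagene over LINE-1 loci -------------------------------------
    regions = [t.locus for t in joined
               if t.te_id in {m.associated_line1 for m in monomers}]
    designated = sim_config.designated_stage
    profiles = {}
    for stage in sim_config.stages:
        mg = binary_metagene(regions,
                             [p.locus for p in peaks.atac[stage]],
                             n_body_bins=50, flank_bp=5000, flank_bins=25)
        profiles[stage] = mg.column_means()
    save("metagene_atac_on_l1.tsv", lambda p: pd.DataFrame(
        profiles).to_csv(p, sep="\t"))
    manifest["designated_stage"] = designated

    # --- expression ----------------------------------------------------
    agg = aggregate_joined(counts, join_map)
    normalized = tmm_normalize(agg)
    # joined ids of all planted young LINE-1s / of the monomer-bearing group
    universe_ids = sorted({join_map.get(fid, fid)
                           for fid in ann.truth.fragment_map})
    group_full = set(ann.truth.l1_group)
    group_ids = sorted({join_map.get(fid, fid)
                        for fid, full in ann.truth.fragment_map.items()
                        if full in group_full})
    expr_res = group_vs_random_expression(
        group_ids, universe_ids, normalized, agg.stages,
        n_perm=n_perm, seed=seed)
    save("l1_group_expression.tsv",
         lambda p: results_to_frame(expr_res).to_csv(p, sep="\t"))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str))
    logger.info("pipeline complete: %d outputs in %s",
                len(manifest["outputs"]), outdir)
    return manifest
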