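"""End-to-end orchestration: simulate (or load) inputs, run every stage,
write all outputs with provenance (config hash + seed), return the report.

Stage order: phenotype summary and bulk selection -> marker selection and
SNP-index -> windowed delta, permutation thresholds, candidate regions ->
variant-effect classification -> differential expression -> intersection
and region refinement -> report.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from . import bsa_mapping, bsa_variants, expression, integrate, io, phenotype
from .config import PipelineConfig
from .simdata import SimConfig, StudyBundle, simulate_study, write_truth_json
from .variant_effect import classify_variants, genes_with_nonsyn_in_regions

logger = logging.getLogger("bulkmap")

__all__ = ["run_pipeline", "run_bsa_stage", "write_study_inputs"]


def write_study_inputs(bundle: StudyBundle, outdir: str, meta: str = "") -> dict:
    """Persist one simulated study as the pipeline's on-disk inputs."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "variants_tsv": os.path.join(outdir, "variants.tsv"),
        "variants_vcf": os.path.join(outdir, "variants.vcf"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "fasta": os.path.join(outdir, "genome.fa"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "lengths": os.path.join(outdir, "gene_lengths.tsv"),
        "heights": os.path.join(outdir, "heights.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    io.write_variants_tsv(bundle.variants, paths["variants_tsv"], meta)
    io.write_variants_vcf(
        bundle.variants, paths["variants_vcf"],
        contigs={c: bundle.cfg.chrom_length_bp for c in bundle.cfg.chrom_names()},
        header_meta=meta,
    )
    io.write_gene_models_gff3(bundle.genes, paths["gff3"])
    io.write_genome_fasta(bundle.genome, paths["fasta"])
    io.write_counts_tsv(bundle.counts, paths["counts"], meta)
    bundle.gene_lengths.to_frame().to_csv(paths["lengths"], sep="\t")
    pd.DataFrame(
        {"id": range(len(bundle.heights)), "height_cm": bundle.heights}
    ).to_csv(paths["heights"], sep="\t", index=False)
    write_truth_json(bundle.truth, paths["truth"])
    return paths


def run_bsa_stage(
    variants: pd.DataFrame, cfg: PipelineConfig, seed: int | None = None
):
    """Marker selection, SNP-index, filters, windows, thresholds, regions.

    Returns (track, profile, regions).  ``seed`` defaults to cfg.seed and
    drives the permutation null only.
    """
    informative = bsa_variants.call_parent_informative_markers(variants)
    logger.info("informative markers: %d / %d", len(informative), len(variants))
    track = bsa_variants.compute_snp_index(informative)
    track = bsa_variants.filter_markers(
        track, index_min=cfg.index_min, depth_min=cfg.depth_min,
        depth_rule=cfg.depth_rule,
    )
    logger.info("markers after filters: %d", len(track))
    profile = bsa_mapping.window_profile(
        track, window_bp=cfg.window_bp, step_bp=cfg.step_bp,
        min_markers=cfg.min_markers,
    )
    profile = bsa_mapping.permutation_threshold(
        track, profile, n_perm=cfg.n_perm, level=cfg.level,
        seed=cfg.seed if seed is None else seed,
    )
    regions = bsa_mapping.call_candidate_regions(profile, track)
    logger.info(
        "windows: %d (%d significant) -> regions: %d",
        len(profile), int(profile["significant"].sum()), len(regions),
    )
    return track, profile, regions


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str,
    sim_cfg: SimConfig | None = None,
    inputs: dict | None = None,
) -> dict:
    """Run every stage and write outputs under ``outdir``.

    Either ``sim_cfg`` (generate the study) or ``inputs`` (paths to
    variants/gff3/fasta/counts/lengths/heights, optionally truth) must be
    given.  Deterministic: identical configs and seeds give byte-identical
    reports.
    """
    if (sim_cfg is None) == (inputs is None):
        raise ValueError("give exactly one of sim_cfg (simulate) or inputs (load)")
    os.makedirs(outdir, exist_ok=True)
    chash = io.config_hash(cfg.to_dict())
    meta = f"config_sha256_12={chash} seed={cfg.seed}"

    if sim_cfg is not None:
        bundle = simulate_study(sim_cfg)
        write_study_inputs(bundle, outdir, meta)
        variants = bundle.variants
        genes, genome = bundle.genes, bundle.genome
        counts, lengths = bundle.counts, bundle.gene_lengths
        heights = bundle.heights
        truth = bundle.truth
    else:
        required = ["variants", "gff3", "fasta", "counts", "lengths", "heights"]
        missing = [k for k in required if k not in inputs]
        if missing:
            raise ValueError(f"missing input paths: {missing}")
        for key in required:
            if not os.path.exists(inputs[key]):
                raise FileNotFoundError(f"{key} input not found: {inputs[key]}")
        variants = io.read_variant_table(inputs["variants"])
        genome = io.read_genome_fasta(inputs["fasta"])
        genes = io.read_gene_models(inputs["gff3"], genome)
        counts = io.read_counts_tsv(inputs["counts"])
        lengths = pd.read_csv(inputs["lengths"], sep="\t", index_col=0).iloc[:, 0]
        heights = pd.read_csv(
            inputs["heights"], sep="\t", float_precision="round_trip"
        )["height_cm"].to_numpy()
        truth = None
        if inputs.get("truth") and os.path.exists(inputs["truth"]):
            import json

            with open(inputs["truth"]) as fh:
                truth = json.load(fh)

    # --- phenotype -----------------------------------------------------
    summary = phenotype.summarize_phenotypes(heights)
    low, high = phenotype.select_bulks(
        heights, list(range(len(heights))), cfg.bulk_size
    )
    logger.info(
        "phenotype: n=%d mean=%.1f sd=%.1f skew=%.3f kurt=%.3f normal=%s",
        summary.n, summary.mean, summary.sd, summary.skewness,
        summary.kurtosis, summary.normal_flag,
    )
    pd.DataFrame(
        {"bulk": ["low"] * len(low) + ["high"] * len(high), "id": low + high}
    ).to_csv(os.path.join(outdir, "bulks.tsv"), sep="\t", index=False)

    # --- BSA -----------------------------------------------------------
    track, profile, regions = run_bsa_stage(variants, cfg)
    io.write_table(track, os.path.join(outdir, "snp_index.tsv"),
                   meta + "; " + bsa_variants.ORIENTATION_NOTE)
    io.write_table(profile, os.path.join(outdir, "window_profile.tsv"), meta)
    io.write_regions_bed(regions, os.path.join(outdir, "regions.bed"), meta)

    # --- variant effects -----------------------------------------------
    effects = classify_variants(variants, genes, genome)
    io.write_table(effects, os.path.join(outdir, "effects.tsv"), meta)
    bsa_genes = genes_with_nonsyn_in_regions(effects, regions)
    logger.info("region genes with protein-changing sites: %d", len(bsa_genes))

    # --- expression ----------------------------------------------------
    sf = expression.size_factors(counts)
    fpkm = expression.compute_fpkm(counts, lengths)
    groups = [c.rsplit("_", 1)[0] for c in counts.columns]
    nb = expression.nb_test(counts, groups, sf, control="XYP1")
    de = expression.call_degs(
        nb, fpkm, lfc_min=cfg.lfc_min, q_max=cfg.q_max, fpkm_min=cfg.fpkm_min
    )
    corr = expression.sample_correlation(counts, sf)
    de.rename_axis("gene_id").reset_index().to_csv(
        os.path.join(outdir, "de_results.tsv"), sep="\t", index=False
    )
    corr.to_csv(os.path.join(outdir, "sample_correlation.tsv"), sep="\t")
    n_deg = int(de["deg_flag"].sum())
    de_counts = {
        "n_deg": n_deg,
        "n_up": int((de["direction"] == "up").sum()),
        "n_down": int((de["direction"] == "down").sum()),
        "n_expressed": int(de["expressed_flag"].sum()),
    }
    logger.info("DEGs: %(n_deg)d (%(n_up)d up / %(n_down)d down)", de_counts)

    # --- integration ---------------------------------------------------
    gene_spans = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "gene_start": [g.gene_start for g in genes],
            "gene_end": [g.gene_end for g in genes],
        }
    )
    assignment = integrate.assign_genes_to_regions(gene_spans, regions)
    bsa_genes = bsa_genes.merge(assignment, on="gene_id", how="left")
    candidates = integrate.intersect_candidates(bsa_genes, de)
    candidates.attrs["n_bsa_genes"] = len(bsa_genes)
    candidates.attrs["n_degs"] = n_deg
    retained = integrate.refine_regions(regions, candidates)
    logger.info(
        "candidates: %d genes; regions retained: %d / %d",
        len(candidates), len(retained), len(regions),
    )

    report = integrate.build_report(
        summary, regions, retained, candidates,
        de_counts=de_counts, truth=truth, config_hash=chash, seed=cfg.seed,
    )
    integrate.write_report(report, os.path.join(outdir, "report.json"))
    io.write_table(candidates, os.path.join(outdir, "candidates.tsv"), meta)
    return report
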