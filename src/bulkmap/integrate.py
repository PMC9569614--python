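"""Intersection of BSA candidate genes with DEGs and the final report.

A final candidate gene must carry protein-changing variants inside a
candidate region AND be differentially expressed.  Regions whose mutated
genes are all unexpressed or non-differential are excluded (mirroring the
exclusion of unsupported preliminary regions), so every retained region
keeps at least one supported gene.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = [
    "assign_genes_to_regions",
    "intersect_candidates",
    "refine_regions",
    "build_report",
    "read_report",
]


def assign_genes_to_regions(
    gene_spans: pd.DataFrame, regions: pd.DataFrame
) -> pd.DataFrame:
    """Map genes to regions by any overlap of gene span with region span.

    ``gene_spans`` needs gene_id, chrom, gene_start, gene_end (1-based
    inclusive).  A gene overlapping several regions is assigned to each.
    """
    rows = []
    for reg in regions.itertuples(index=False):
        hit = gene_spans[
            (gene_spans["chrom"] == reg.chrom)
            & (gene_spans["gene_start"] <= int(reg.end))
            & (gene_spans["gene_end"] >= int(reg.start))
        ]
        for gid in hit["gene_id"]:
            rows.append((gid, reg.region_id))
    return pd.DataFrame(rows, columns=["gene_id", "region_id"])


def _check_id_overlap(left: set, right: set) -> None:
    if not left or not right or (left & right):
        return
    norm = lambda s: {str(x).strip().casefold() for x in s}  # noqa: E731
    if norm(left) & norm(right):
        raise ValueError(
            "gene id formats disagree between BSA and expression inputs "
            "(ids match only after case/whitespace normalization); "
            f"examples: {sorted(left)[:3]} vs {sorted(right)[:3]}"
        )


def intersect_candidates(
    bsa_genes: pd.DataFrame, de_results: pd.DataFrame
) -> pd.DataFrame:
    """Exact intersection of mutated region genes with called DEGs.

    ``bsa_genes`` carries gene_id, n_sites and (optionally) region_id;
    ``de_results`` is the call_degs output indexed by gene_id.  Attributes
    from both sides are joined; only genes with deg_flag survive.
    """
    degs = de_results.loc[de_results["deg_flag"] == True]  # noqa: E712
    _check_id_overlap(set(bsa_genes["gene_id"]), set(degs.index))
    merged = bsa_genes.merge(
        degs[["log2fc", "q", "direction"]], left_on="gene_id", right_index=True
    )
    return merged.sort_values("gene_id").reset_index(drop=True)


def refine_regions(
    regions: pd.DataFrame, candidates: pd.DataFrame
) -> pd.DataFrame:
    """Keep only regions with >= 1 intersected candidate gene.

    A region whose mutated genes are all unexpressed or not differentially
    expressed has no member in ``candidates`` and is dropped.  Never adds
    regions.
    """
    if "region_id" not in candidates.columns or candidates.empty:
        return regions.iloc[0:0].reset_index(drop=True)
    keep = regions["region_id"].isin(set(candidates["region_id"]))
    return regions.loc[keep].reset_index(drop=True)


def build_report(
    phenotype_summary,
    regions: pd.DataFrame,
    retained_regions: pd.DataFrame,
    candidates: pd.DataFrame,
    de_counts: dict | None = None,
    truth: dict | None = None,
    config_hash: str = "",
    seed: int | None = None,
) -> dict:
    """Machine-readable end-of-pipeline report.

    When a simulation truth record is present, ``true_qtl_recovered`` says
    whether the planted QTL position falls inside a retained region.
    """
    def _records(df: pd.DataFrame) -> list[dict]:
        clean = df.drop(columns=["member_variants"], errors="ignore")
        return json.loads(clean.to_json(orient="records"))

    report = {
        "config_hash": config_hash,
        "seed": seed,
        "phenotype": {
            "n": phenotype_summary.n,
            "mean": phenotype_summary.mean,
            "sd": phenotype_summary.sd,
            "skewness": phenotype_summary.skewness,
            "kurtosis": phenotype_summary.kurtosis,
            "normal_flag": phenotype_summary.normal_flag,
        },
        "regions": _records(regions),
        "retained_regions": _records(retained_regions),
        "candidate_genes": _records(candidates),
        "venn": {
            "n_bsa_genes": int(candidates.attrs.get("n_bsa_genes", 0)),
            "n_degs": int(candidates.attrs.get("n_degs", 0)),
            "n_intersection": int(len(candidates)),
        },
    }
    if de_counts:
        report["de_counts"] = de_counts
    if truth is not None:
        qtl = truth.get("qtl", {})
        inside = any(
            r["chrom"] == qtl.get("chrom") and r["start"] <= qtl.get("pos", -1) <= r["end"]
            for r in report["retained_regions"]
        )
        report["truth"] = {"qtl": qtl, "true_qtl_recovered": bool(inside)}
    return report


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
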