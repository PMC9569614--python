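"""File formats: variant tables (VCF 4.2 / TSV dialect), gene models
(GFF3 + FASTA), counts matrices, BED export and coordinate converters.

External coordinates are 1-based inclusive (VCF/GFF convention); BED output
is 0-based half-open.  Reading uses established parsers (cyvcf2, gffutils,
Biopython); writing emits plain uncompressed text.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import VARIANT_COLUMNS
from .variant_effect import GeneModel

__all__ = [
    "read_variant_table",
    "write_variants_tsv",
    "write_variants_vcf",
    "read_gene_models",
    "write_gene_models_gff3",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_regions_bed",
    "to_bed_interval",
    "from_bed_interval",
    "config_hash",
    "write_table",
]

_SAMPLES = ("XYP1", "AYP1", "F2H", "F2L")


# ---------------------------------------------------------------- coordinates

def to_bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def from_bed_interval(start_0based: int, end_0based: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start_0based + 1, end_0based


# ------------------------------------------------------------- variant tables

def write_variants_tsv(df: pd.DataFrame, path: str, header_meta: str = "") -> None:
    with open(path, "w") as fh:
        if header_meta:
            fh.write(f"# {header_meta}\n")
        df[VARIANT_COLUMNS].to_csv(fh, sep="\t", index=False)


def _read_variants_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if df.empty and df.columns.size == 0:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[VARIANT_COLUMNS].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lineno = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}: malformed/truncated record at line {lineno}")
    for col in ("pos", "hb_ref", "hb_alt", "lb_ref", "lb_alt"):
        df[col] = df[col].astype(np.int64)
    return df[VARIANT_COLUMNS + [c for c in df.columns if c not in VARIANT_COLUMNS]]


def write_variants_vcf(
    df: pd.DataFrame,
    path: str,
    contigs: dict[str, int] | None = None,
    header_meta: str = "",
) -> None:
    """Emit VCF 4.2 with parent GT and per-bulk AD/DP.

    Sample order: XYP1 (tall parent), AYP1 (dwarf parent), F2H, F2L.
    Parent depths come from p1_dp/p2_dp columns when present, else the
    genotype is written with a nominal depth of 10.
    """
    if contigs is None:
        contigs = {
            str(c): int(df.loc[df["chrom"] == c, "pos"].max()) if len(df) else 0
            for c in pd.unique(df["chrom"]) if len(df)
        }
    p1_dp = df["p1_dp"] if "p1_dp" in df.columns else pd.Series(10, index=df.index)
    p2_dp = df["p2_dp"] if "p2_dp" in df.columns else pd.Series(10, index=df.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bulkmap\n")
        if header_meta:
            fh.write(f"##bulkmap_meta={header_meta}\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(_SAMPLES) + "\n")
        for i, rec in enumerate(df.itertuples(index=False)):
            d1, d2 = int(p1_dp.iloc[i]), int(p2_dp.iloc[i])
            p1_ad = (d1, 0) if rec.p1_gt.startswith("0") else (0, d1)
            p2_ad = (d2, 0) if rec.p2_gt.startswith("0") else (0, d2)
            cols = [
                rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS", ".",
                "GT:AD:DP",
                f"{rec.p1_gt}:{p1_ad[0]},{p1_ad[1]}:{d1}",
                f"{rec.p2_gt}:{p2_ad[0]},{p2_ad[1]}:{d2}",
                f"./.:{rec.hb_ref},{rec.hb_alt}:{rec.hb_ref + rec.hb_alt}",
                f"./.:{rec.lb_ref},{rec.lb_alt}:{rec.lb_ref + rec.lb_alt}",
            ]
            fh.write("\t".join(cols) + "\n")


def _read_variants_vcf(
    path: str, samples: tuple[str, str, str, str] = _SAMPLES
) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path)
    names = list(vcf.samples)
    try:
        idx = [names.index(s) for s in samples]
    except ValueError as exc:
        raise ValueError(f"{path}: expected samples {samples}, found {names}") from exc
    ip1, ip2, ih, il = idx
    rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # biallelic only
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"{path}: AD field missing at {v.CHROM}:{v.POS} "
                f"(needed for bulk samples {samples[2]}/{samples[3]})"
            )
        gts = [_gt_string(v.genotypes[i]) for i in (ip1, ip2)]
        rows.append(
            (
                v.CHROM, v.POS, v.REF, v.ALT[0], gts[0], gts[1],
                max(int(ad[ih][0]), 0), max(int(ad[ih][1]), 0),
                max(int(ad[il][0]), 0), max(int(ad[il][1]), 0),
            )
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _gt_string(gt_entry) -> str:
    a, b = gt_entry[0], gt_entry[1]
    sep = "|" if (len(gt_entry) > 2 and gt_entry[2]) else "/"
    fa = "." if a < 0 else str(a)
    fb = "." if b < 0 else str(b)
    return f"{fa}{sep}{fb}"


def read_variant_table(path: str, dialect: str | None = None) -> pd.DataFrame:
    """Read a variant table; dialect inferred from the extension
    ('.vcf' vs anything else = TSV) unless given explicitly."""
    if dialect is None:
        dialect = "vcf" if str(path).endswith(".vcf") else "tsv"
    if dialect == "vcf":
        return _read_variants_vcf(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------- gene models

def write_gene_models_gff3(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.gene_start)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tbulkmap\tgene\t{g.gene_start}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tbulkmap\tmRNA\t{g.gene_start}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            segments = sorted(g.cds_segments)
            # GFF3 phase: leading bases to discard before the next full codon
            done = 0
            ordered = segments if g.strand == "+" else segments[::-1]
            phases = {}
            for a, b in ordered:
                phases[(a, b)] = (3 - done % 3) % 3
                done += b - a + 1
            for a, b in segments:
                fh.write(
                    f"{g.chrom}\tbulkmap\tCDS\t{a}\t{b}\t.\t{g.strand}\t"
                    f"{phases[(a, b)]}\tID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
                )


def read_gene_models(
    gff_path: str, genome: dict[str, str] | None = None
) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/CDS features).

    With multiple isoforms the one with the longest CDS is kept.  Minus
    strand CDS segments are ordered 5'->3' after load.  A CDS whose total
    length is not divisible by 3 raises, naming the gene.
    """
    import gffutils

    if os.path.getsize(gff_path) == 0 or not _has_features(gff_path):
        return []
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            if sum(b - a + 1 for a, b in segs) > sum(b - a + 1 for a, b in best):
                best = segs
        if not best:  # CDS directly under gene
            best = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
        if not best:
            continue
        ordered = sorted(best) if gene.strand == "+" else sorted(best, key=lambda s: -s[0])
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            cds_segments=ordered,
            gene_start=gene.start,
            gene_end=gene.end,
        )
        model.validate_frame()
        if genome is not None:
            model.extract_cds(genome)
        genes.append(model)
    return genes


def _has_features(path: str) -> bool:
    with open(path) as fh:
        return any(line.strip() and not line.startswith("#") for line in fh)


# --------------------------------------------------------------------- FASTA

def write_genome_fasta(genome: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_genome_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# --------------------------------------------------------------------- counts

def write_counts_tsv(counts: pd.DataFrame, path: str, header_meta: str = "") -> None:
    with open(path, "w") as fh:
        if header_meta:
            fh.write(f"# {header_meta}\n")
        counts.to_csv(fh, sep="\t")


def read_counts_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene_id"
    return df


# ----------------------------------------------------------------------- BED

def write_regions_bed(regions: pd.DataFrame, path: str, header_meta: str = "") -> None:
    """Candidate regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        if header_meta:
            fh.write(f"# {header_meta}\n")
        for reg in regions.itertuples(index=False):
            s0, e0 = to_bed_interval(int(reg.start), int(reg.end))
            fh.write(f"{reg.chrom}\t{s0}\t{e0}\t{reg.region_id}\n")


# -------------------------------------------------------------------- config

def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping, for output provenance."""
    payload = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str, meta: str = "") -> None:
    """TSV with a provenance comment header (config hash + seed)."""
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        df.to_csv(fh, sep="\t", index=False)
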