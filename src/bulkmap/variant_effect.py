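"""Codon-level effect classification of SNVs against gene models.

Replaces the usual external annotator with a transparent classifier: each
biallelic SNV is located relative to the gene models, the affected codon is
extracted from the cached CDS, the alternate allele is substituted
(reverse-complemented on minus-strand genes) and both codons are translated
with the standard genetic code.  Exonic calls are one of ``synonymous``,
``non-synonymous``, ``stop-gain`` or ``stop-loss``; variants inside a gene
span but outside its CDS are ``intronic``; everything else is
``intergenic``.

Only single-nucleotide substitutions on biallelic sites are supported.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "EffectCall",
    "CODING_EFFECTS",
    "classify_variant",
    "classify_variants",
    "genes_with_nonsyn_in_regions",
]

#: effect classes that change the protein
CODING_EFFECTS = frozenset({"non-synonymous", "stop-gain", "stop-loss"})

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One gene with a single coding isoform.

    ``cds_segments`` are 1-based inclusive genomic intervals ordered 5'->3'
    along the transcript (descending genomic coordinate on the minus
    strand).  ``gene_start``/``gene_end`` bound the full gene span, which may
    exceed the CDS (UTRs / introns collapse into the gene body here).
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_segments: list[tuple[int, int]]
    gene_start: int = 0
    gene_end: int = 0
    cds_seq: str = ""  # cached spliced CDS, transcript orientation

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.cds_segments:
            raise ValueError(f"gene {self.gene_id}: no CDS segments")
        genomic = sorted(self.cds_segments)
        for (a1, b1), (a2, b2) in zip(genomic, genomic[1:]):
            if a2 <= b1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS segments")
        if not self.gene_start:
            self.gene_start = min(a for a, _ in self.cds_segments)
        if not self.gene_end:
            self.gene_end = max(b for _, b in self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)

    def validate_frame(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    def extract_cds(self, genome: dict[str, str]) -> str:
        """Splice and orient the CDS from chromosome sequence; caches result."""
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[a - 1 : b] for a, b in sorted(self.cds_segments)]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        self.cds_seq = seq
        return seq

    def cds_offset(self, pos: int) -> int | None:
        """0-based transcript offset of genomic position ``pos``, or None
        when the position falls outside every CDS segment."""
        offset = 0
        segments = self.cds_segments
        if self.strand == "+":
            for a, b in sorted(segments):
                if a <= pos <= b:
                    return offset + (pos - a)
                offset += b - a + 1
        else:
            for a, b in sorted(segments, key=lambda s: -s[0]):
                if a <= pos <= b:
                    return offset + (b - pos)
                offset += b - a + 1
        return None


@dataclass
class EffectCall:
    variant_id: str
    gene_id: str | None
    effect: str
    codon_ref: str = ""
    codon_alt: str = ""
    aa_ref: str = ""
    aa_alt: str = ""


class _GeneIndex:
    """Per-chromosome bisect index over non-overlapping gene spans."""

    def __init__(self, genes: list[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for chrom in {g.chrom for g in genes}:
            sub = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.gene_start)
            for g1, g2 in zip(sub, sub[1:]):
                if g2.gene_start <= g1.gene_end:
                    raise ValueError(
                        f"overlapping genes {g1.gene_id}/{g2.gene_id} on {chrom}"
                    )
            self._by_chrom[chrom] = ([g.gene_start for g in sub], sub)

    def lookup(self, chrom: str, pos: int) -> GeneModel | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, sub = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and sub[i].gene_start <= pos <= sub[i].gene_end:
            return sub[i]
        return None


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: list[GeneModel] | _GeneIndex,
    genome: dict[str, str],
) -> EffectCall:
    """Classify one SNV.  ``pos`` is 1-based.

    Raises ``ValueError`` when the stated reference allele disagrees with the
    chromosome sequence (a coordinate-system bug detector).
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"{chrom}:{pos} not an SNV ({ref}>{alt})")
    genome_base = genome[chrom][pos - 1].upper()
    if genome_base != ref.upper():
        raise ValueError(
            f"{chrom}:{pos} ref allele {ref} disagrees with genome base {genome_base}"
        )
    vid = f"{chrom}:{pos}"
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    gene = index.lookup(chrom, pos)
    if gene is None:
        return EffectCall(vid, None, "intergenic")
    offset = gene.cds_offset(pos)
    if offset is None:
        return EffectCall(vid, gene.gene_id, "intronic")
    cds = gene.cds_seq or gene.extract_cds(genome)
    alt_base = alt.upper() if gene.strand == "+" else reverse_complement(alt.upper())
    codon_i, within = divmod(offset, 3)
    codon_ref = cds[3 * codon_i : 3 * codon_i + 3]
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
    aa_ref, aa_alt = _translate(codon_ref), _translate(codon_alt)
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stop-gain"
    elif aa_ref == "*":
        effect = "stop-loss"
    else:
        effect = "non-synonymous"
    return EffectCall(vid, gene.gene_id, effect, codon_ref, codon_alt, aa_ref, aa_alt)


def classify_variants(
    variants: pd.DataFrame, genes: list[GeneModel], genome: dict[str, str]
) -> pd.DataFrame:
    """Classify every row of a variant table (``chrom,pos,ref,alt`` columns).

    Returns one row per variant: variant_id, chrom, pos, gene_id, effect,
    aa_ref, aa_alt.
    """
    index = _GeneIndex(genes)
    rows = []
    for rec in variants.itertuples(index=False):
        call = classify_variant(rec.chrom, int(rec.pos), rec.ref, rec.alt, index, genome)
        rows.append(
            (call.variant_id, rec.chrom, int(rec.pos), call.gene_id, call.effect,
             call.aa_ref, call.aa_alt)
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "gene_id", "effect", "aa_ref", "aa_alt"]
    )


def genes_with_nonsyn_in_regions(
    effects: pd.DataFrame, regions: pd.DataFrame
) -> pd.DataFrame:
    """Genes carrying >=1 protein-changing SNV inside any candidate region.

    ``effects`` is the classify_variants output; ``regions`` has
    ``chrom,start,end`` (1-based inclusive).  Returns gene_id with the count
    of qualifying sites per gene, descending by count.
    """
    if effects.empty or regions.empty:
        return pd.DataFrame(columns=["gene_id", "n_sites"])
    coding = effects[effects["effect"].isin(CODING_EFFECTS)]
    if coding.empty:
        return pd.DataFrame(columns=["gene_id", "n_sites"])
    keep = pd.Series(False, index=coding.index)
    for reg in regions.itertuples(index=False):
        keep |= (
            (coding["chrom"] == reg.chrom)
            & (coding["pos"] >= int(reg.start))
            & (coding["pos"] <= int(reg.end))
        )
    hit = coding[keep]
    out = (
        hit.groupby("gene_id").size().rename("n_sites").reset_index()
        .sort_values(["n_sites", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out
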