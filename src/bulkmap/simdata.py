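"""Synthetic F2-cross study generator.

Emulates a bulked-segregant + RNA-seq study design on a bi-parental cross
between two fully inbred lines: a tall reference parent (XYP1, carrying
allele 0 at every marker) and a dwarf parent (AYP1, allele 1).  Defaults
follow the emulated study: an F2 population of 200 plants with a normally
distributed height controlled by one major additive QTL, two extreme bulks
of 30 plants each, parents sequenced at ~10x and bulks at ~50x.

The generator produces, at desk scale:

* F2 genotype dosages via Haldane recombination (no interference),
* phenotypes = baseline + additive QTL effect + Gaussian environment
  (the default effect is negative per dwarf-allele dose, so AYP1's allele
  shortens the plant),
* parent + bulk allele-depth tables (Poisson depth, binomial allele
  sampling with a symmetric sequencing-error flip),
* non-overlapping single-CDS gene models with chromosome sequence,
* negative-binomial RNA-seq counts with planted fold changes,

plus a truth record (QTL position, planted differentially expressed genes)
so downstream recovery can be scored.  All randomness flows from explicit
``numpy`` Generators; identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .variant_effect import GeneModel, reverse_complement

__all__ = [
    "SimConfig",
    "F2Genotypes",
    "simulate_gametes",
    "simulate_f2_population",
    "simulate_phenotypes",
    "simulate_bulk_reads",
    "simulate_null_reads",
    "simulate_gene_models",
    "simulate_rnaseq_counts",
    "simulate_study",
    "StudyBundle",
]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "p1_gt", "p2_gt",
    "hb_ref", "hb_alt", "lb_ref", "lb_alt",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic cross.

    Units: positions/lengths in bp, recombination in cM/Mb, phenotype in cm,
    depths in reads.  Defaults are the emulated study's design values where
    the study states them (population and bulk sizes, depths); the QTL
    effect and environmental spread are free parameters chosen to give a
    major-effect locus (about half the phenotypic variance).
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    n_markers_per_chrom: int = 2000
    recomb_rate: float = 4.0              # cM per Mb
    qtl_position: tuple[str, int] = ("chr1", 1_000_000)
    qtl_effect: float = -15.0             # cm per dwarf-allele dose (dwarfing)
    dominance: float = 0.0                # cm added to heterozygotes
    baseline: float = 100.0               # cm
    env_sd: float = 10.0                  # cm
    pop_size: int = 200
    bulk_size: int = 30
    parent_depth_mean: float = 10.0
    bulk_depth_mean: float = 50.0
    seq_error: float = 0.01
    n_genes_per_chrom: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_markers_per_chrom", "pop_size",
                     "bulk_size", "n_genes_per_chrom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")
        if self.parent_depth_mean < 0 or self.bulk_depth_mean < 0:
            raise ValueError("depth means must be >= 0")
        if 2 * self.bulk_size > self.pop_size:
            raise ValueError("2*bulk_size must not exceed pop_size")
        chrom, pos = self.qtl_position
        if chrom not in self.chrom_names() or not 1 <= pos <= self.chrom_length_bp:
            raise ValueError(f"qtl_position {self.qtl_position} outside simulated genome")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class F2Genotypes:
    """Dosage matrix (individuals x markers) of the dwarf-parent allele."""

    dosage: np.ndarray            # (n, m) int8, values in {0, 1, 2}
    chrom: np.ndarray             # (m,) str
    pos: np.ndarray               # (m,) int

    def __post_init__(self) -> None:
        if self.dosage.size and not np.isin(self.dosage, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {c}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def marker_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]


def haldane_recomb_fraction(d_morgans: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function r = (1 - exp(-2d)) / 2 for map distance d (Morgans)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def simulate_gametes(
    positions_bp: np.ndarray,
    recomb_cm_per_mb: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` gametes from an F1 over one chromosome.

    Each gamete is a 0/1 haplotype; crossovers between adjacent markers occur
    with the Haldane probability for their map distance, independently across
    intervals (no interference).
    """
    positions_bp = np.asarray(positions_bp, dtype=np.int64)
    if np.any(np.diff(positions_bp) < 0):
        raise ValueError("marker positions must be non-decreasing")
    m = positions_bp.size
    start = rng.integers(0, 2, size=n, dtype=np.int8)
    if m == 0:
        return np.empty((n, 0), dtype=np.int8)
    d = np.diff(positions_bp) / 1e6 * recomb_cm_per_mb / 100.0  # Morgans
    r = haldane_recomb_fraction(d)
    switches = rng.random((n, m - 1)) < r
    flips = np.zeros((n, m), dtype=np.int8)
    flips[:, 1:] = np.cumsum(switches, axis=1) % 2
    return (start[:, None] ^ flips).astype(np.int8)


def simulate_f2_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> F2Genotypes:
    """F2 genotypes = sum of two independent F1 gametes per chromosome."""
    rng = rng if rng is not None else cfg.rng()
    chroms, positions, blocks = [], [], []
    for name in cfg.chrom_names():
        pos = np.sort(
            rng.choice(
                np.arange(1, cfg.chrom_length_bp + 1),
                size=min(cfg.n_markers_per_chrom, cfg.chrom_length_bp),
                replace=False,
            )
        )
        g1 = simulate_gametes(pos, cfg.recomb_rate, cfg.pop_size, rng)
        g2 = simulate_gametes(pos, cfg.recomb_rate, cfg.pop_size, rng)
        blocks.append(g1 + g2)
        chroms.append(np.full(pos.size, name, dtype=object))
        positions.append(pos)
    if not blocks:
        return F2Genotypes(np.empty((cfg.pop_size, 0), dtype=np.int8),
                           np.empty(0, dtype=object), np.empty(0, dtype=np.int64))
    return F2Genotypes(
        np.hstack(blocks).astype(np.int8),
        np.concatenate(chroms),
        np.concatenate(positions).astype(np.int64),
    )


def qtl_marker_index(geno: F2Genotypes, qtl_position: tuple[str, int]) -> int:
    """Index of the marker nearest the QTL on its chromosome."""
    chrom, pos = qtl_position
    on = np.flatnonzero(geno.chrom == chrom)
    if on.size == 0:
        raise ValueError(f"no markers on QTL chromosome {chrom}")
    return int(on[np.argmin(np.abs(geno.pos[on] - pos))])


def simulate_phenotypes(
    geno: F2Genotypes, cfg: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Height per individual: baseline + additive (and optional dominance)
    QTL effect applied at the marker nearest the QTL, plus N(0, env_sd)."""
    if cfg.env_sd < 0:
        raise ValueError("env_sd must be >= 0")
    rng = rng if rng is not None else cfg.rng()
    dose = geno.dosage[:, qtl_marker_index(geno, cfg.qtl_position)].astype(float)
    heights = cfg.baseline + cfg.qtl_effect * dose + cfg.dominance * (dose == 1)
    return heights + rng.normal(0.0, cfg.env_sd, size=geno.n_individuals)


def _assign_alleles(
    chrom: np.ndarray, pos: np.ndarray,
    genome: dict[str, str] | None, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Ref = tall-parent allele (genome base when available), alt = dwarf allele."""
    m = pos.size
    if genome is None:
        ref = np.full(m, "A", dtype=object)
    else:
        ref = np.array([genome[c][p - 1] for c, p in zip(chrom, pos)], dtype=object)
    shift = rng.integers(1, 4, size=m)
    base_idx = np.array(["ACGT".index(b) for b in ref])
    alt = np.array(["ACGT"[i] for i in (base_idx + shift) % 4], dtype=object)
    return ref, alt


def _sample_reads(
    p_true: np.ndarray, depth_mean: float, seq_error: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(depth_mean, size=p_true.size)
    p_obs = p_true * (1.0 - seq_error) + (1.0 - p_true) * seq_error
    alt = rng.binomial(depth, p_obs)
    return depth, alt


def simulate_bulk_reads(
    geno: F2Genotypes,
    high_bulk: np.ndarray,
    low_bulk: np.ndarray,
    cfg: SimConfig,
    genome: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pooled sequencing of the two extreme bulks plus the inbred parents.

    Per marker and bulk the true alt (dwarf-allele) frequency is the mean
    dosage / 2; depth is Poisson(bulk_depth_mean) and alt reads are
    Binomial(depth, p') with p' the error-flipped frequency.  Parents are
    emitted as fixed opposite homozygotes (tall parent 0/0, dwarf 1/1) with
    Poisson(parent_depth_mean) depth.
    """
    high_bulk = np.asarray(high_bulk, dtype=int)
    low_bulk = np.asarray(low_bulk, dtype=int)
    if high_bulk.size == 0 or low_bulk.size == 0:
        raise ValueError("bulk index sets must be non-empty")
    if np.intersect1d(high_bulk, low_bulk).size:
        raise ValueError("bulk index sets must be disjoint")
    rng = rng if rng is not None else cfg.rng()

    ref, alt = _assign_alleles(geno.chrom, geno.pos, genome, rng)
    p_high = geno.dosage[high_bulk].mean(axis=0) / 2.0
    p_low = geno.dosage[low_bulk].mean(axis=0) / 2.0
    dp_h, alt_h = _sample_reads(p_high, cfg.bulk_depth_mean, cfg.seq_error, rng)
    dp_l, alt_l = _sample_reads(p_low, cfg.bulk_depth_mean, cfg.seq_error, rng)
    m = geno.n_markers
    df = pd.DataFrame(
        {
            "chrom": geno.chrom,
            "pos": geno.pos,
            "ref": ref,
            "alt": alt,
            "p1_gt": np.full(m, "0/0", dtype=object),
            "p2_gt": np.full(m, "1/1", dtype=object),
            "hb_ref": dp_h - alt_h,
            "hb_alt": alt_h,
            "lb_ref": dp_l - alt_l,
            "lb_alt": alt_l,
        }
    )
    df["p1_dp"] = rng.poisson(cfg.parent_depth_mean, size=m)
    df["p2_dp"] = rng.poisson(cfg.parent_depth_mean, size=m)
    return df


def simulate_null_reads(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Marker-level no-linkage null: both bulks sequenced at true allele
    fraction 0.5 everywhere, so only read-sampling noise separates them.
    This is the null the read re-splitting permutation scheme models."""
    rng = rng if rng is not None else cfg.rng()
    chroms, positions = [], []
    for name in cfg.chrom_names():
        pos = np.sort(
            rng.choice(np.arange(1, cfg.chrom_length_bp + 1),
                       size=min(cfg.n_markers_per_chrom, cfg.chrom_length_bp),
                       replace=False)
        )
        chroms.append(np.full(pos.size, name, dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    pos = (np.concatenate(positions) if positions else np.empty(0)).astype(np.int64)
    m = pos.size
    half = np.full(m, 0.5)
    dp_h, alt_h = _sample_reads(half, cfg.bulk_depth_mean, cfg.seq_error, rng)
    dp_l, alt_l = _sample_reads(half, cfg.bulk_depth_mean, cfg.seq_error, rng)
    ref, alt = _assign_alleles(chrom, pos, None, rng)
    return pd.DataFrame(
        {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "p1_gt": np.full(m, "0/0", dtype=object),
            "p2_gt": np.full(m, "1/1", dtype=object),
            "hb_ref": dp_h - alt_h, "hb_alt": alt_h,
            "lb_ref": dp_l - alt_l, "lb_alt": alt_l,
        }
    )


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def simulate_gene_models(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], dict[str, str]]:
    """Non-overlapping single-CDS genes on both strands, plus chromosome
    sequence with each CDS embedded so extraction round-trips.

    Genes sit in evenly spaced slots with random jitter; each CDS is
    100-299 codons (frame-complete, ATG start, stop end) flanked by 100 bp
    of untranslated gene body on each side.
    """
    rng = rng if rng is not None else cfg.rng()
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    flank = 100
    for name in cfg.chrom_names():
        seq = rng.choice(_BASES, size=cfg.chrom_length_bp).tobytes().decode()
        seq = list(seq)
        if cfg.n_genes_per_chrom:
            slot = cfg.chrom_length_bp // cfg.n_genes_per_chrom
            for i in range(cfg.n_genes_per_chrom):
                n_codons = int(rng.integers(100, 300))
                cds_len = 3 * n_codons
                lo = i * slot + flank + 1
                hi = (i + 1) * slot - cds_len - flank
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                end = start + cds_len - 1
                strand = "+" if rng.random() < 0.5 else "-"
                cds = _random_cds(n_codons, rng)
                embedded = cds if strand == "+" else reverse_complement(cds)
                seq[start - 1 : end] = list(embedded)
                genes.append(
                    GeneModel(
                        gene_id=f"{name}g{i + 1:04d}",
                        chrom=name,
                        strand=strand,
                        cds_segments=[(start, end)],
                        gene_start=start - flank,
                        gene_end=end + flank,
                    )
                )
        genome[name] = "".join(seq)
    for g in genes:
        g.extract_cds(genome)
        g.validate_frame()
    return genes, genome


def simulate_rnaseq_counts(
    gene_ids: list[str],
    de_plan: dict[str, float],
    n_reps: int = 3,
    dispersion: float = 0.1,
    mean_log_mu: float = 5.0,
    sd_log_mu: float = 1.0,
    rng: np.random.Generator | None = None,
    condition_names: tuple[str, str] = ("XYP1", "AYP1"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Negative-binomial counts for two conditions (control first).

    Per gene, mean mu_g ~ LogNormal(mean_log_mu, sd_log_mu); the treated
    condition mean is mu_g * 2**log2fc for planted genes.  Counts follow
    NB with var = mu + dispersion * mu^2 (Poisson when dispersion == 0).
    Returns the genes x samples matrix and the planted-truth map.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    unknown = set(de_plan) - set(gene_ids)
    if unknown:
        raise ValueError(f"de_plan genes not in gene set: {sorted(unknown)[:5]}")
    rng = rng if rng is not None else np.random.default_rng(0)
    g = len(gene_ids)
    mu = rng.lognormal(mean_log_mu, sd_log_mu, size=g)
    lfc = np.array([de_plan.get(gid, 0.0) for gid in gene_ids])

    def draw(mean: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mean)
        n = 1.0 / dispersion
        return rng.negative_binomial(n, n / (n + mean))

    data = {}
    for r in range(n_reps):
        data[f"{condition_names[0]}_{r + 1}"] = draw(mu)
    for r in range(n_reps):
        data[f"{condition_names[1]}_{r + 1}"] = draw(mu * 2.0 ** lfc)
    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return counts, dict(de_plan)


@dataclass
class StudyBundle:
    """Everything one synthetic study produces, in memory."""

    cfg: SimConfig
    geno: F2Genotypes
    heights: np.ndarray
    low_bulk: np.ndarray
    high_bulk: np.ndarray
    variants: pd.DataFrame
    genes: list[GeneModel]
    genome: dict[str, str]
    counts: pd.DataFrame
    gene_lengths: pd.Series
    truth: dict = field(default_factory=dict)


def default_de_plan(
    genes: list[GeneModel],
    cfg: SimConfig,
    rng: np.random.Generator,
    qtl_halo_bp: int = 300_000,
    background_frac: float = 0.05,
    planted_lfc: float = 2.0,
) -> dict[str, float]:
    """Plant fold changes: genes near the QTL are down in the dwarf line
    (|log2FC| = planted_lfc); a sprinkling of background genes move in
    random directions, mimicking trans effects."""
    chrom, qpos = cfg.qtl_position
    plan: dict[str, float] = {}
    for g in genes:
        if g.chrom == chrom and abs((g.gene_start + g.gene_end) // 2 - qpos) <= qtl_halo_bp:
            plan[g.gene_id] = -planted_lfc
    others = [g.gene_id for g in genes if g.gene_id not in plan]
    n_bg = int(round(background_frac * len(others)))
    for gid in rng.choice(others, size=n_bg, replace=False):
        plan[gid] = planted_lfc * (1.0 if rng.random() < 0.5 else -1.0)
    return plan


def simulate_study(cfg: SimConfig) -> StudyBundle:
    """Run the whole generator with one seed: genotypes, phenotypes, bulks,
    bulk sequencing, gene models + genome, RNA-seq counts, truth record."""
    from . import phenotype as _ph  # local import avoids a cycle at module load

    root = np.random.SeedSequence(cfg.seed)
    r_geno, r_phen, r_reads, r_genes, r_counts, r_plan = (
        np.random.default_rng(s) for s in root.spawn(6)
    )
    geno = simulate_f2_population(cfg, r_geno)
    heights = simulate_phenotypes(geno, cfg, r_phen)
    ids = list(range(cfg.pop_size))
    low, high = _ph.select_bulks(heights, ids, cfg.bulk_size)
    genes, genome = simulate_gene_models(cfg, r_genes)
    variants = simulate_bulk_reads(
        geno, np.array(high), np.array(low), cfg, genome=genome, rng=r_reads
    )
    plan = default_de_plan(genes, cfg, r_plan)
    counts, truth_de = simulate_rnaseq_counts(
        [g.gene_id for g in genes], plan, rng=r_counts
    )
    lengths = pd.Series(
        {g.gene_id: g.cds_length for g in genes}, name="length_bp"
    ).rename_axis("gene_id")
    truth = {
        "qtl": {"chrom": cfg.qtl_position[0], "pos": int(cfg.qtl_position[1])},
        "planted_degs": truth_de,
        "seed": cfg.seed,
    }
    return StudyBundle(
        cfg=cfg, geno=geno, heights=heights,
        low_bulk=np.array(low), high_bulk=np.array(high),
        variants=variants, genes=genes, genome=genome,
        counts=counts, gene_lengths=lengths, truth=truth,
    )


def write_truth_json(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
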