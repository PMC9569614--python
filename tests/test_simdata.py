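"""Generator checks: Haldane recombination, phenotype variance
decomposition, read-sampling moments, gene-model invariants, NB counts."""

import numpy as np
import pandas as pd
import pytest

from bulkmap.simdata import (
    F2Genotypes,
    SimConfig,
    haldane_recomb_fraction,
    simulate_bulk_reads,
    simulate_f2_population,
    simulate_gametes,
    simulate_gene_models,
    simulate_phenotypes,
    simulate_rnaseq_counts,
    simulate_study,
)
from bulkmap.variant_effect import reverse_complement


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SimConfig(seq_error=0.5)
        with pytest.raises(ValueError):
            SimConfig(env_sd=-1)
        with pytest.raises(ValueError):
            SimConfig(pop_size=10, bulk_size=6)
        with pytest.raises(ValueError):
            SimConfig(qtl_position=("chr9", 100))

    def test_genotypes_reject_non_increasing_positions(self):
        with pytest.raises(ValueError, match="increasing"):
            F2Genotypes(
                np.zeros((2, 2), dtype=np.int8),
                np.array(["chr1", "chr1"]),
                np.array([100, 100]),
            )


class TestGametes:
    def test_identical_positions_give_identical_columns(self, rng):
        g = simulate_gametes(np.array([500, 500]), 4.0, 200, rng)
        assert np.array_equal(g[:, 0], g[:, 1])

    def test_haldane_recombinant_fraction_at_100cm(self, rng):
        # two markers 100 cM apart: 1 Mb at 100 cM/Mb
        n = 10_000
        g = simulate_gametes(np.array([1, 1_000_001]), 100.0, n, rng)
        r_obs = np.mean(g[:, 0] != g[:, 1])
        r_true = haldane_recomb_fraction(1.0)  # (1 - e^-2) / 2
        se = np.sqrt(r_true * (1 - r_true) / n)
        assert abs(r_obs - r_true) < 3 * se

    def test_empty_population_allowed(self):
        cfg = SimConfig(pop_size=0, bulk_size=0, n_markers_per_chrom=10,
                        chrom_length_bp=10_000, qtl_position=("chr1", 5000))
        geno = simulate_f2_population(cfg)
        assert geno.dosage.shape == (0, 20)

    def test_dosages_within_bounds(self, small_study):
        assert set(np.unique(small_study.geno.dosage)) <= {0, 1, 2}


class TestPhenotypes:
    def test_no_effect_no_noise_gives_baseline(self, rng):
        cfg = SimConfig(qtl_effect=0.0, env_sd=0.0, n_markers_per_chrom=50,
                        chrom_length_bp=100_000, qtl_position=("chr1", 50_000))
        geno = simulate_f2_population(cfg, rng)
        h = simulate_phenotypes(geno, cfg, rng)
        assert np.allclose(h, cfg.baseline)

    def test_same_seed_reproducible(self):
        cfg = SimConfig(n_markers_per_chrom=50, chrom_length_bp=100_000,
                        qtl_position=("chr1", 50_000), seed=3)
        h1 = simulate_phenotypes(simulate_f2_population(cfg), cfg)
        h2 = simulate_phenotypes(simulate_f2_population(cfg), cfg)
        assert np.array_equal(h1, h2)

    def test_variance_decomposition(self, rng):
        # F2 additive variance at allele freq 1/2 is a^2/2; total a^2/2 + s^2
        a, s = 12.0, 5.0
        cfg = SimConfig(pop_size=10_000, bulk_size=10, qtl_effect=a, env_sd=s,
                        n_markers_per_chrom=20, chrom_length_bp=100_000,
                        qtl_position=("chr1", 50_000))
        geno = simulate_f2_population(cfg, rng)
        h = simulate_phenotypes(geno, cfg, rng)
        expected = a**2 / 2 + s**2
        assert abs(np.var(h, ddof=1) - expected) / expected < 0.05

    def test_negative_env_sd_rejected(self, small_study):
        cfg = SimConfig()
        cfg.env_sd = -1.0
        with pytest.raises(ValueError):
            simulate_phenotypes(small_study.geno, cfg)


class TestBulkReads:
    def test_fixed_allele_zero_error(self, rng):
        cfg = SimConfig(seq_error=0.0, n_markers_per_chrom=100,
                        chrom_length_bp=100_000, qtl_position=("chr1", 50_000),
                        pop_size=20, bulk_size=5)
        geno = simulate_f2_population(cfg, rng)
        geno.dosage[:] = 0  # p = 0 everywhere
        df = simulate_bulk_reads(geno, np.arange(5), np.arange(5, 10), cfg, rng=rng)
        assert (df["hb_alt"] == 0).all() and (df["lb_alt"] == 0).all()

    def test_zero_depth_mean(self, rng):
        cfg = SimConfig(bulk_depth_mean=0.0, n_markers_per_chrom=50,
                        chrom_length_bp=100_000, qtl_position=("chr1", 50_000),
                        pop_size=20, bulk_size=5)
        geno = simulate_f2_population(cfg, rng)
        df = simulate_bulk_reads(geno, np.arange(5), np.arange(5, 10), cfg, rng=rng)
        assert (df[["hb_ref", "hb_alt", "lb_ref", "lb_alt"]] == 0).all().all()

    def test_mean_alt_fraction_at_half(self, rng):
        cfg = SimConfig(seq_error=0.0, n_markers_per_chrom=10_000,
                        chrom_length_bp=1_000_000, n_chromosomes=1,
                        qtl_position=("chr1", 500_000), pop_size=2, bulk_size=1)
        geno = simulate_f2_population(cfg, rng)
        geno.dosage[:] = 1  # every individual het -> p = 0.5 exactly
        df = simulate_bulk_reads(geno, np.array([0]), np.array([1]), cfg, rng=rng)
        frac = df["hb_alt"].sum() / (df["hb_alt"] + df["hb_ref"]).sum()
        n_reads = (df["hb_alt"] + df["hb_ref"]).sum()
        se = np.sqrt(0.25 / n_reads)
        assert abs(frac - 0.5) < 3 * se

    def test_bulk_validation(self, small_study):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_bulk_reads(small_study.geno, np.array([], dtype=int),
                                np.array([1]), small_study.cfg)
        with pytest.raises(ValueError, match="disjoint"):
            simulate_bulk_reads(small_study.geno, np.array([1, 2]),
                                np.array([2, 3]), small_study.cfg)


class TestGeneModels:
    def test_constructed_invariants(self, small_study):
        genes = small_study.genes
        assert genes, "generator produced no genes"
        for g in genes:
            assert g.cds_length % 3 == 0
            assert g.cds_seq.startswith("ATG")
            assert g.cds_seq[-3:] in {"TAA", "TAG", "TGA"}
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.gene_start, g.gene_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 > e1, "genes overlap"

    def test_cds_extraction_matches_embedding(self, small_study):
        for g in small_study.genes:
            seq = small_study.genome[g.chrom]
            a, b = g.cds_segments[0] if g.strand == "+" else g.cds_segments[-1]
            lo = min(s[0] for s in g.cds_segments)
            hi = max(s[1] for s in g.cds_segments)
            raw = seq[lo - 1 : hi]
            expected = raw if g.strand == "+" else reverse_complement(raw)
            assert g.cds_seq == expected


class TestRnaseqCounts:
    def test_zero_dispersion_is_poisson_like(self, rng):
        counts, _ = simulate_rnaseq_counts(
            ["g1"], {}, n_reps=5000, dispersion=0.0, sd_log_mu=0.0, rng=rng
        )
        x = counts.to_numpy().ravel()
        assert abs(x.var() / x.mean() - 1.0) < 0.1

    def test_null_plan_symmetric_means(self, rng):
        genes = [f"g{i}" for i in range(2000)]
        counts, _ = simulate_rnaseq_counts(genes, {}, n_reps=3, rng=rng)
        a = counts.filter(like="XYP1").to_numpy().mean()
        b = counts.filter(like="AYP1").to_numpy().mean()
        assert abs(a - b) / a < 0.05

    def test_planted_fold_change_recovered(self, rng):
        counts, truth = simulate_rnaseq_counts(
            ["g1"], {"g1": 2.0}, n_reps=1000, dispersion=0.1,
            mean_log_mu=np.log(500.0), sd_log_mu=0.0, rng=rng,
        )
        ratio = counts.filter(like="AYP1").to_numpy().mean() / counts.filter(
            like="XYP1"
        ).to_numpy().mean()
        assert abs(ratio - 4.0) / 4.0 < 0.05
        assert truth == {"g1": 2.0}

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            simulate_rnaseq_counts(["g1"], {}, n_reps=0)
        with pytest.raises(ValueError):
            simulate_rnaseq_counts(["g1"], {}, dispersion=-0.1)
        with pytest.raises(ValueError):
            simulate_rnaseq_counts(["g1"], {"nope": 1.0})


class TestStudyBundle:
    def test_seeded_runs_identical(self, small_cfg):
        b1 = simulate_study(small_cfg)
        b2 = simulate_study(small_cfg)
        assert np.array_equal(b1.geno.dosage, b2.geno.dosage)
        assert np.array_equal(b1.heights, b2.heights)
        pd.testing.assert_frame_equal(b1.variants, b2.variants)
        pd.testing.assert_frame_equal(b1.counts, b2.counts)

    def test_high_bulk_enriched_for_tall_allele_at_qtl(self, small_study):
        # dwarf-allele dosage at the QTL should be lower in the tall bulk
        from bulkmap.simdata import qtl_marker_index

        i = qtl_marker_index(small_study.geno, small_study.cfg.qtl_position)
        dose_high = small_study.geno.dosage[small_study.high_bulk, i].mean()
        dose_low = small_study.geno.dosage[small_study.low_bulk, i].mean()
        assert dose_high < dose_low
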