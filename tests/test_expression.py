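"""FPKM, size factors, the NB Wald test, BH, DEG calls, enrichment,
correlation QC and the qPCR transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bulkmap.expression import (
    bh_adjust,
    call_degs,
    compute_fpkm,
    ddct,
    hypergeometric_enrichment,
    nb_test,
    sample_correlation,
    size_factors,
)


def _counts(mat, samples=None, genes=None):
    mat = np.asarray(mat)
    samples = samples or [f"s{i}" for i in range(mat.shape[1])]
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=genes, columns=samples)


class TestFpkm:
    def test_direct_formula(self):
        counts = _counts([[100]])
        lengths = pd.Series({"g0": 1000})
        libs = pd.Series({"s0": 1_000_000})
        assert compute_fpkm(counts, lengths, libs).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_count_zero_fpkm(self):
        out = compute_fpkm(_counts([[0], [10]]), pd.Series({"g0": 500, "g1": 500}))
        assert out.iloc[0, 0] == 0.0

    def test_scale_invariance(self):
        counts = _counts([[10, 20], [30, 40]])
        lengths = pd.Series({"g0": 100, "g1": 2000})
        libs = counts.sum(axis=0)
        a = compute_fpkm(counts, lengths, libs)
        b = compute_fpkm(2 * counts, lengths, 2 * libs)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            compute_fpkm(_counts([[0]]), pd.Series({"g0": 100}))


class TestSizeFactors:
    def test_identical_samples_unity(self):
        counts = _counts([[10, 10], [5, 5], [100, 100]])
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_sample_factor_two(self, rng):
        base = rng.poisson(100, size=500) + 1
        counts = _counts(np.column_stack([base, 2 * base]))
        sf = size_factors(counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_bruteforce_median_of_ratios(self, rng):
        mat = rng.poisson(50, size=(300, 4)) + 1
        sf = size_factors(_counts(mat))
        logs = np.log(mat)
        geo = np.exp(logs.mean(axis=1))
        expected = np.median(mat / geo[:, None], axis=0)
        np.testing.assert_allclose(sf.to_numpy(), expected)

    def test_gene_reordering_invariant(self, rng):
        mat = rng.poisson(50, size=(100, 3)) + 1
        counts = _counts(mat)
        perm = rng.permutation(100)
        np.testing.assert_allclose(
            size_factors(counts).to_numpy(),
            size_factors(counts.iloc[perm]).to_numpy(),
        )

    def test_no_qualifying_gene_rejected(self):
        with pytest.raises(ValueError):
            size_factors(_counts([[0, 5], [3, 0]]))


class TestNbTest:
    GROUPS = ["XYP1"] * 3 + ["AYP1"] * 3

    def test_identical_groups_null(self):
        mat = np.tile([[100, 120, 110]], (5, 2)).reshape(5, 6)
        counts = _counts(mat, samples=[f"XYP1_{i}" for i in range(3)]
                         + [f"AYP1_{i}" for i in range(3)])
        out = nb_test(counts, self.GROUPS, pd.Series(1.0, index=counts.columns))
        np.testing.assert_allclose(out["log2fc"], 0.0, atol=1e-12)
        assert (out["p"] > 0.9).all()

    def test_group_size_validation(self):
        counts = _counts([[1, 2, 3]], samples=["a", "b", "c"])
        with pytest.raises(ValueError):
            nb_test(counts, ["XYP1", "XYP1", "AYP1"],
                    pd.Series(1.0, index=counts.columns))

    def test_direction_of_planted_change(self, rng):
        mu = np.full(200, 200.0)
        c0 = rng.poisson(mu[:, None], (200, 3))
        c1 = rng.poisson(4 * mu[:, None], (200, 3))
        counts = _counts(np.hstack([c0, c1]),
                         samples=[f"XYP1_{i}" for i in range(3)]
                         + [f"AYP1_{i}" for i in range(3)])
        out = nb_test(counts, self.GROUPS, pd.Series(1.0, index=counts.columns))
        assert (out["log2fc"] > 1).all()
        assert out.attrs["case"] == "AYP1"


class TestBh:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_bruteforce_definition(self, rng):
        p = rng.random(10_000)
        q = bh_adjust(p)
        m = p.size
        order = np.argsort(p)
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(1, m + 1)
        brute = np.array(
            [min(1.0, np.min((p * m / ranks)[p >= p[i] - 1e-15])) for i in
             rng.choice(m, 200, replace=False)]
        )
        idx = rng.choice(m, 200, replace=False)
        # recompute brute for the same indices
        brute = np.array(
            [min(1.0, (p * m / ranks)[p >= p[i]].min()) for i in idx]
        )
        np.testing.assert_allclose(q[idx], brute, rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_permutation_invariance(self, ps):
        p = np.asarray(ps)
        q = bh_adjust(p)
        perm = np.random.default_rng(0).permutation(p.size)
        q_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], rtol=1e-12)


class TestDegCall:
    def _results(self, lfc, q_target):
        df = pd.DataFrame(
            {"baseMean": 100.0, "log2fc": lfc, "dispersion": 0.1,
             "stat": 0.0, "p": q_target},
            index=[f"g{i}" for i in range(len(lfc))],
        )
        return df

    def test_strict_thresholds(self):
        # |lfc| exactly 1 or q exactly 0.05 are NOT DEGs
        res = self._results([1.0, 1.2, -1.2, 2.0], [0.001, 0.001, 0.001, 0.05])
        out = call_degs(res)
        # single-m BH keeps q == p here only when monotone; check flags
        assert not out.loc["g0", "deg_flag"]          # lfc boundary
        assert out.loc["g1", "deg_flag"]
        assert out.loc["g1", "direction"] == "up"
        assert out.loc["g2", "direction"] == "down"

    def test_q_boundary_strict(self):
        res = self._results([3.0], [0.05])
        out = call_degs(res)
        assert out.loc["g0", "q"] == pytest.approx(0.05)
        assert not out.loc["g0", "deg_flag"]

    def test_matches_bruteforce_predicate(self, rng):
        n = 400
        res = self._results(rng.normal(0, 2, n), rng.random(n))
        fpkm = pd.DataFrame(
            rng.gamma(1, 2, size=(n, 4)), index=res.index,
            columns=["XYP1_1", "XYP1_2", "AYP1_1", "AYP1_2"],
        )
        out = call_degs(res, fpkm)
        for gid in res.index:
            expect = abs(out.loc[gid, "log2fc"]) > 1 and out.loc[gid, "q"] < 0.05
            assert out.loc[gid, "deg_flag"] == expect
            assert out.loc[gid, "expressed_flag"] == (fpkm.loc[gid] > 1).any()


class TestEnrichment:
    def test_whole_universe_term_p_one(self):
        uni = {f"g{i}" for i in range(10)}
        out = hypergeometric_enrichment({"g1", "g2"}, uni, {"t": set(uni)})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_tail(self):
        # universe 10, term 5, draw 4, overlap 4
        uni = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        degs = {"g0", "g1", "g2", "g3"}
        out = hypergeometric_enrichment(degs, uni, {"t": term})
        from math import comb

        total = comb(10, 4)
        p_exact = sum(comb(5, k) * comb(5, 4 - k) for k in (4,)) / total
        assert out["p"].iloc[0] == pytest.approx(p_exact)

    def test_disjoint_term_p_one(self):
        uni = {f"g{i}" for i in range(10)}
        out = hypergeometric_enrichment({"g0"}, uni, {"t": {"g8", "g9"}})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_degs_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"g1"}, {})


class TestCorrelation:
    def test_duplicated_sample_r_one(self, rng):
        base = rng.poisson(100, 200) + 1
        counts = _counts(np.column_stack([base, base, rng.poisson(100, 200) + 1]))
        r = sample_correlation(counts)
        assert r.iloc[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)

    def test_matches_textbook_formula(self, rng):
        mat = rng.poisson(80, size=(150, 3)) + 1
        counts = _counts(mat)
        sf = pd.Series(1.0, index=counts.columns)
        r = sample_correlation(counts, sf)
        x = np.log2(mat + 1.0)
        expected = np.corrcoef(x, rowvar=False)
        np.testing.assert_allclose(r.to_numpy(), expected)

    def test_zero_variance_rejected(self):
        counts = _counts([[1, 1], [1, 2]])
        with pytest.raises(ValueError):
            sample_correlation(counts, pd.Series(1.0, index=counts.columns))


class TestDdct:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((20, 15, 25, 20), 1.0),    # ddCt = 0
            ((25, 20, 24, 20), 0.5),    # ddCt = 1
            ((24, 20, 26, 20), 4.0),    # ddCt = -2
        ],
    )
    def test_closed_form(self, args, expected):
        assert ddct(*args) == pytest.approx(expected)

    def test_control_condition_is_unity(self):
        assert ddct(24.0, 19.0, 24.0, 19.0) == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct(np.inf, 20, 24, 20)
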