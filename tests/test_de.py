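"""Differential expression: size factors, dispersion, exact test, BH, FPKM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import frontload as fl
from frontload import de as D
from frontload.errors import ConfigError, DataError
from frontload.simulate import SimConfig, generate_dataset

from conftest import toy_counts


# ----------------------------------------------------------------------
# size factors & normalization
# ----------------------------------------------------------------------
class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = toy_counts([[5, 5], [9, 9], [100, 100]])
        assert np.allclose(D.estimate_size_factors(cm), 1.0)

    def test_doubled_column_gives_sqrt2_factors(self):
        cm = toy_counts([[5, 10], [9, 18], [100, 200]])
        sf = D.estimate_size_factors(cm)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_gene_row_hand_computation(self):
        cm = toy_counts([[4, 9]])
        sf = D.estimate_size_factors(cm)
        assert np.allclose(sf, [4 / 6, 9 / 6])  # geometric mean 6

    def test_no_all_positive_row_is_an_error(self):
        cm = toy_counts([[0, 5], [9, 0]])
        with pytest.raises(DataError, match="pseudo-reference"):
            D.estimate_size_factors(cm)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_column_scaling_equivariance(self, c):
        base = pd.DataFrame(
            np.array([[5, 7, 9], [11, 13, 17], [100, 90, 80], [3, 4, 5]]),
            columns=list("abc"),
            dtype=float,
        )
        sf0 = D.estimate_size_factors(base)
        scaled = base.copy()
        scaled["b"] *= c
        sf1 = D.estimate_size_factors(scaled)
        # relative factors are what normalization uses; the scaled column's
        # factor grows by c relative to every untouched column
        assert (sf1["b"] / sf1["a"]) / (sf0["b"] / sf0["a"]) == pytest.approx(
            c, rel=1e-9
        )

    def test_recovers_planted_library_size_spread(self):
        lsf = [0.5, 1.0, 2.0] * 4
        cfg = SimConfig(
            n_genes=2000, archetype_counts={}, dispersion=0.02,
            library_size_factors=lsf, seed=13,
        )
        cm, _ = generate_dataset(cfg)
        sf = D.estimate_size_factors(cm).to_numpy()
        rel = sf / np.exp(np.mean(np.log(sf)))
        expected = np.asarray(lsf) / np.exp(np.mean(np.log(lsf)))
        assert np.allclose(rel, expected, rtol=0.06)

    def test_idempotence_after_normalization(self):
        cm = toy_counts([[5, 10], [9, 18], [100, 200]])
        sf = D.estimate_size_factors(cm)
        norm = D.normalize(cm, sf)
        sf2 = D.estimate_size_factors(norm)
        assert np.allclose(sf2, 1.0, atol=1e-9)


class TestNormalize:
    def test_unit_factors_leave_matrix_unchanged(self):
        cm = toy_counts([[10, 20]])
        out = D.normalize(cm, pd.Series([1.0, 1.0], index=cm.counts.columns))
        assert np.allclose(out, [[10, 20]])

    def test_forced_arithmetic(self):
        cm = toy_counts([[10, 20]])
        out = D.normalize(cm, pd.Series([1.0, 2.0], index=cm.counts.columns))
        assert np.allclose(out, [[10, 10]])

    def test_nonpositive_factor_rejected(self):
        cm = toy_counts([[10, 20]])
        with pytest.raises(DataError):
            D.normalize(cm, pd.Series([1.0, 0.0], index=cm.counts.columns))


# ----------------------------------------------------------------------
# dispersion
# ----------------------------------------------------------------------
class TestDispersion:
    def test_hand_computed_method_of_moments(self):
        # qbar = 15, pooled within-group variance 50 -> (50-15)/225
        a = pd.DataFrame([[10.0, 20.0]])
        b = pd.DataFrame([[10.0, 20.0]])
        alpha = D.estimate_dispersion(a, b, moderation="none")
        assert alpha.iloc[0] == pytest.approx(35 / 225)

    def test_variance_below_mean_floors_at_zero(self):
        a = pd.DataFrame([[100.0, 100.0, 100.0]])
        b = pd.DataFrame([[100.0, 100.0, 100.0]])
        assert D.estimate_dispersion(a, b, moderation="none").iloc[0] == 0.0

    def test_poisson_limit_small_alpha(self, rng):
        x = rng.poisson(100, size=10_000).astype(float)
        a = pd.DataFrame(x[:5000][None, :])
        b = pd.DataFrame(x[5000:][None, :])
        alpha = D.estimate_dispersion(a, b, moderation="none").iloc[0]
        assert 0.0 <= alpha <= 0.01

    def test_zero_mean_gene_flagged_nan(self):
        a = pd.DataFrame([[0.0, 0.0], [5.0, 7.0]])
        b = pd.DataFrame([[0.0, 0.0], [6.0, 8.0]])
        alpha = D.estimate_dispersion(a, b)
        assert np.isnan(alpha.iloc[0]) and np.isfinite(alpha.iloc[1])

    def test_max_median_moderation_floors_low_estimates(self):
        a = pd.DataFrame([[100.0, 100.0], [10.0, 40.0], [200.0, 350.0]])
        b = pd.DataFrame([[100.0, 100.0], [15.0, 35.0], [250.0, 300.0]])
        raw = D.estimate_dispersion(a, b, moderation="none")
        mod = D.estimate_dispersion(a, b, moderation="max_median")
        med = np.nanmedian(raw)
        assert (mod >= np.minimum(raw, med) - 1e-15).all()
        assert mod.iloc[0] == pytest.approx(med)  # zero-variance gene pulled up


# ----------------------------------------------------------------------
# exact test
# ----------------------------------------------------------------------
class TestExactTest:
    def test_symmetric_modal_observation_gives_p_one(self):
        assert D.nb_exact_test(5, 5, 5.0, 5.0, 0.1, 0.1) == 1.0

    def test_zero_total_gives_p_one(self):
        assert D.nb_exact_test(0, 0, 3.0, 3.0, 0.0, 0.0) == 1.0

    @pytest.mark.parametrize("sum_a,sum_b,n_a,n_b", [(0, 10, 2, 2), (3, 17, 3, 3), (8, 2, 1, 3)])
    def test_poisson_case_matches_binomial(self, sum_a, sum_b, n_a, n_b):
        total = sum_a + sum_b
        p_impl = D.nb_exact_test(sum_a, sum_b, float(n_a), float(n_b), 0.0, 0.0)
        # direct binomial enumeration with the same tie rule
        pr = n_a / (n_a + n_b)
        pmf = stats.binom.pmf(np.arange(total + 1), total, pr)
        p_ref = pmf[pmf <= pmf[sum_a] * (1 + 1e-9)].sum()
        assert p_impl == pytest.approx(p_ref, abs=1e-12)

    def test_large_totals_switch_to_normal_approximation(self):
        # p from the approximation should be close to the exact one near the cap
        exact = D.nb_exact_test(5200, 4800, 5000.0, 5000.0, 0.001, 0.001)
        approx = D.nb_exact_test(5200, 4800, 5000.0, 5000.0, 0.001, 0.001, cap=1000)
        assert approx == pytest.approx(exact, rel=0.05)

    def test_rejects_bad_arguments(self):
        with pytest.raises(DataError):
            D.nb_exact_test(-1, 5, 3.0, 3.0, 0.0, 0.0)
        with pytest.raises(DataError):
            D.nb_exact_test(1, 5, 3.0, 3.0, -0.1, 0.0)


# ----------------------------------------------------------------------
# BH adjustment
# ----------------------------------------------------------------------
def bh_bruteforce(p):
    """Explicit sort + min-scan step-up (independent oracle)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for j in range(m):
        out[order[j]] = min(
            min(m * p[order[l]] / (l + 1) for l in range(j, m)), 1.0
        )
    return out


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert D.bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_examples(self):
        assert np.allclose(D.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(D.bh_adjust([0.005, 0.1, 0.9]), [0.015, 0.15, 0.9])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            D.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_bruteforce_and_dominates_p(self, p):
        adj = D.bh_adjust(p)
        assert np.allclose(adj, bh_bruteforce(p), atol=0, rtol=0)
        assert (adj >= np.asarray(p) - 1e-15).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(D.bh_adjust(p), ref, atol=1e-12)


# ----------------------------------------------------------------------
# signed fold change
# ----------------------------------------------------------------------
class TestSignedFoldChange:
    def test_equal_means_give_plus_one(self):
        assert D.signed_fold_change(7.0, 7.0) == 1.0

    def test_forced_arithmetic_without_pseudocount(self):
        assert D.signed_fold_change(2.0, 10.0, pseudocount=0.0) == 5.0
        assert D.signed_fold_change(10.0, 2.0, pseudocount=0.0) == -5.0

    @given(
        st.floats(min_value=0.0, max_value=1e4),
        st.floats(min_value=0.0, max_value=1e4),
    )
    def test_antisymmetry_and_magnitude_bound(self, a, b):
        fc = D.signed_fold_change(a, b)
        assert abs(fc) >= 1.0
        if abs(fc) > 1.0:
            assert D.signed_fold_change(b, a) == pytest.approx(-fc)


# ----------------------------------------------------------------------
# full contrast & FPKM
# ----------------------------------------------------------------------
class TestRunContrast:
    def test_self_contrast_rejected(self, null_dataset):
        cm, _ = null_dataset
        with pytest.raises(DataError, match="overlap"):
            fl.run_contrast(cm, "T13_C", "T13_C")

    def test_empty_group_rejected(self, null_dataset):
        cm, _ = null_dataset
        with pytest.raises(DataError):
            fl.run_contrast(cm, cm.group("T13_C"), [])

    def test_low_count_genes_not_tested(self, null_dataset):
        cm, _ = null_dataset
        cm2 = fl.CountMatrix(cm.counts.copy(), cm.samples.copy())
        cm2.counts.iloc[0] = 0
        cm2.counts.iloc[0, 0] = 4  # total 4 < 10
        res = fl.run_contrast(cm2, "T13_C", "T13_T")
        first = res.iloc[0]
        assert not first["tested"] and first["p"] == 1.0 and first["padj"] == 1.0
        assert first["direction"] == "none"

    def test_planted_tenfold_gene_is_called_up(self, null_dataset):
        cm, _ = null_dataset
        cm2 = fl.CountMatrix(cm.counts.copy(), cm.samples.copy())
        t_cols = cm2.group("T13_T")
        cm2.counts.loc[cm2.genes[0], t_cols] *= 10
        res = fl.run_contrast(cm2, "T13_C", "T13_T")
        assert res.iloc[0]["is_deg"] and res.iloc[0]["direction"] == "up"

    def test_deg_calls_consistent_with_padj_and_direction(self, planted_catalog):
        res = planted_catalog.results["R13"]
        assert (res["is_deg"] == (res["tested"] & (res["padj"] < 0.05))).all()
        deg = res[res["is_deg"]]
        assert ((deg["direction"] == "up") == (deg["log2fc"] > 0)).all()
        assert (res["padj"] >= res["p"] - 1e-15).all()


class TestFpkm:
    def _cm(self):
        cm = toy_counts([[100, 0], [999_900, 1000]])
        cm.lengths = pd.Series([1000.0, 100_000.0], index=cm.genes)
        return cm

    def test_direct_formula(self):
        fpkm = D.compute_fpkm(self._cm())
        # k=100, L=1000 bp, N=1e6 -> 1e9*100/(1000*1e6) = 100
        assert fpkm.iloc[0, 0] == pytest.approx(100.0)
        assert fpkm.iloc[0, 1] == 0.0

    def test_column_scaling_invariance(self):
        cm = self._cm()
        scaled = fl.CountMatrix(cm.counts * 3, cm.samples, lengths=cm.lengths)
        pd.testing.assert_frame_equal(
            D.compute_fpkm(cm), D.compute_fpkm(scaled), atol=1e-9
        )

    def test_zero_column_sum_rejected(self):
        cm = toy_counts([[5, 0]])
        cm.lengths = pd.Series([1000.0], index=cm.genes)
        with pytest.raises(DataError, match="zero total"):
            D.compute_fpkm(cm)

    def test_missing_lengths_rejected(self):
        with pytest.raises(DataError, match="lengths"):
            D.compute_fpkm(toy_counts([[5, 5]]))
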