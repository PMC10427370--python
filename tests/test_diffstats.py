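import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmcresponse.diffstats import (bh_adjust, basic_tests, filter_degs,
                                   filter_dhmgs, nb_wald_test, rlog_approx,
                                   size_factors, tpm, DifferentialResult)
from hmcresponse.io import CountMatrix


def brute_force_size_factors(mat: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios: per sample, median over all-nonzero
    genes of count / geometric mean."""
    nonzero = (mat > 0).all(axis=1)
    sub = mat[nonzero].astype(float)
    geo = np.exp(np.log(sub).mean(axis=1))
    return np.array([np.median(sub[:, j] / geo) for j in range(mat.shape[1])])


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """min over k >= rank(i) of m*p_(k)/k, from the definition."""
    m = len(p)
    order = np.argsort(p)
    out = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [m * p[order[k]] / (k + 1) for k in range(pos, m)]
        out[i] = min(1.0, min(candidates))
    return out


class TestSizeFactors:
    def test_hand_example(self, toy_counts):
        sf = size_factors(toy_counts)
        np.testing.assert_allclose(sf.to_numpy(),
                                   [1 / np.sqrt(2), np.sqrt(2)], atol=1e-4)

    def test_identical_samples_give_unity(self):
        cm = CountMatrix(pd.DataFrame({"a": [5, 9], "b": [5, 9], "c": [5, 9]},
                                      index=["g1", "g2"]))
        np.testing.assert_allclose(size_factors(cm).to_numpy(), 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        mat = rng.negative_binomial(10, 0.1, size=(500, 10))
        cm = CountMatrix(pd.DataFrame(
            mat, index=[f"g{i}" for i in range(500)],
            columns=[f"s{j}" for j in range(10)]))
        np.testing.assert_allclose(size_factors(cm).to_numpy(),
                                   brute_force_size_factors(mat), atol=1e-12)

    def test_no_common_gene_is_error(self):
        cm = CountMatrix(pd.DataFrame({"a": [0, 5], "b": [5, 0]},
                                      index=["g1", "g2"]))
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(cm)


class TestTpm:
    def test_single_gene_is_million(self):
        cm = CountMatrix(pd.DataFrame({"s": [7]}, index=["g"]))
        out = tpm(cm, pd.Series({"g": 2.0}))
        assert out.values.iloc[0, 0] == pytest.approx(1e6)

    def test_length_weighting(self):
        cm = CountMatrix(pd.DataFrame({"s": [10, 10]}, index=["a", "b"]))
        out = tpm(cm, pd.Series({"a": 1.0, "b": 2.0}))
        np.testing.assert_allclose(out.values["s"].to_numpy(),
                                   [2e6 / 3, 1e6 / 3], rtol=1e-6)

    def test_columns_sum_to_million(self, bulk_cohort, lengths):
        counts, _, _ = bulk_cohort
        out = tpm(counts, lengths)
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, atol=1e-4)

    def test_missing_length_names_gene(self, toy_counts):
        with pytest.raises(ValueError, match="b"):
            tpm(toy_counts, pd.Series({"a": 1.0, "c": 1.0}))


class TestRlogApprox:
    def test_zero_count_maps_to_zero(self):
        cm = CountMatrix(pd.DataFrame({"a": [0, 8], "b": [0, 8]},
                                      index=["g1", "g2"]))
        out = rlog_approx(cm)
        assert out.values.loc["g1"].tolist() == [0.0, 0.0]

    def test_depth_invariance_at_large_counts(self):
        rng = np.random.default_rng(1)
        base = rng.integers(100, 2000, size=50)
        cm = CountMatrix(pd.DataFrame(
            {"s1": base, "s2": base * 2, "s3": base},
            index=[f"g{i}" for i in range(50)]))
        out = rlog_approx(cm)
        np.testing.assert_allclose(out.values["s2"], out.values["s1"],
                                   atol=0.02)

    def test_monotone_within_sample(self, bulk_cohort):
        counts, _, _ = bulk_cohort
        out = rlog_approx(counts)
        col = counts.sample_ids[0]
        order = counts.values[col].argsort().to_numpy()
        transformed = out.values[col].to_numpy()[order]
        assert (np.diff(transformed) >= 0).all()


def _nb_matrix(rng, mu, dispersion, n, prefix):
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu[:, None]),
                                   (mu.size, n))
    return counts


class TestNbWaldTest:
    def test_identical_groups_zero_lfc(self):
        rng = np.random.default_rng(2)
        mat = rng.negative_binomial(10, 0.05, size=(100, 3))
        doubled = np.hstack([mat, mat])
        cm = CountMatrix(pd.DataFrame(
            doubled, index=[f"g{i}" for i in range(100)],
            columns=[f"s{j}" for j in range(6)]))
        res = nb_wald_test(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (res.table["log2_fc"] == 0.0).all()

    def test_group_overlap_rejected(self, bulk_cohort):
        counts, _, _ = bulk_cohort
        s = list(counts.sample_ids[:4])
        with pytest.raises(ValueError, match="overlap"):
            nb_wald_test(counts, s[:2], s[1:3])

    def test_single_sample_group_rejected(self, bulk_cohort):
        counts, _, _ = bulk_cohort
        s = list(counts.sample_ids[:4])
        with pytest.raises(ValueError, match="fewer than 2"):
            nb_wald_test(counts, s[:1], s[1:3])

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(3)
        n_bg, n_pl, n = 1800, 200, 10
        mu = np.r_[rng.lognormal(np.log(300), 0.8, n_bg),
                   np.full(n_pl, 500.0)]
        fold = np.r_[np.ones(n_bg), np.full(n_pl, 2.0)]
        a = _nb_matrix(rng, mu, 0.01, n, "a")
        b = _nb_matrix(rng, mu * fold, 0.01, n, "b")
        genes = [f"g{i}" for i in range(n_bg + n_pl)]
        cm = CountMatrix(pd.DataFrame(
            np.hstack([a, b]), index=genes,
            columns=[f"s{j}" for j in range(2 * n)]))
        res = nb_wald_test(cm, [f"s{j}" for j in range(n)],
                           [f"s{j}" for j in range(n, 2 * n)])
        planted = res.table.iloc[n_bg:]
        assert np.median(np.abs(planted["log2_fc"] - 1.0)) < 0.1
        # planted up-genes recovered with high sensitivity by the DEG filter
        hits = set(filter_degs(res)["up"])
        assert len(hits & set(genes[n_bg:])) / n_pl > 0.9

    def test_sign_flips_when_groups_swapped(self, bulk_cohort):
        counts, _, _ = bulk_cohort
        s = list(counts.sample_ids)
        res_ab = nb_wald_test(counts, s[:4], s[4:8])
        res_ba = nb_wald_test(counts, s[4:8], s[:4])
        np.testing.assert_allclose(res_ab.table["log2_fc"],
                                   -res_ba.table["log2_fc"], atol=1e-10)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            mine = bh_adjust(p)
            np.testing.assert_allclose(mine, brute_force_bh(p), atol=1e-12)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, ps, rnd):
        p = np.array(ps)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = bh_adjust(p)[perm]
        permuted = bh_adjust(p[perm])
        np.testing.assert_allclose(direct, permuted, atol=1e-12)


class TestFilters:
    @staticmethod
    def _result(p, padj, lfc):
        table = pd.DataFrame({
            "log2_fc": lfc, "se": 0.1, "p": p, "padj": padj,
            "mean_expr": 100.0}, index=[f"g{i}" for i in range(len(p))])
        return DifferentialResult(table, ["a1", "a2"], ["b1", "b2"])

    def test_deg_thresholds_inclusive(self):
        res = self._result(p=[0.001, 0.001], padj=[0.1, 0.05],
                           lfc=[0.5, 0.3])
        assert filter_degs(res)["all"] == ["g0"]

    def test_dhmg_p_strict(self):
        res = self._result(p=[0.01, 0.0099], padj=[0.5, 0.5],
                           lfc=[2.0, 2.0])
        assert filter_dhmgs(res) == ["g1"]

    def test_dhmg_lfc_inclusive(self):
        res = self._result(p=[0.001, 0.001], padj=[0.5, 0.5],
                           lfc=[0.5, 0.49])
        assert filter_dhmgs(res) == ["g0"]


class TestBasicTests:
    def test_identical_groups(self):
        t, p = basic_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "t_paired")
        assert (t, p) == (0.0, 1.0)

    def test_wilcoxon_exact_enumeration(self):
        # all 3-subsets of 6 ranks: one-sided p = 1/20, two-sided 0.1
        _, p = basic_tests([1, 2, 3], [4, 5, 6], "wilcoxon_ranksum")
        assert p == pytest.approx(0.1)

    def test_all_tied_rank_sum(self):
        _, p = basic_tests([5.0, 5.0], [5.0, 5.0], "wilcoxon_ranksum")
        assert p == 1.0

    def test_paired_shift_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        shift = 3.0 * x.std()
        _, p = basic_tests(x + shift, x, "t_paired")
        assert p < 0.05

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            basic_tests([1, 2], [1, 2, 3], "t_paired")
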