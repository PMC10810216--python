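import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistrokit.nbstats import (
    CountMatrix,
    NBTestResult,
    anova_bonferroni,
    bh_fdr,
    classify,
    estimate_dispersion,
    ks_test_two_sample,
    nb_wald_test,
    size_factors,
)


def make_matrix(counts, reps_a=None, reps_b=None, conditions=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    if conditions is None:
        conditions = ["A"] * reps_a + ["B"] * reps_b
    cols = [f"s{i}" for i in range(n)]
    return CountMatrix(
        pd.DataFrame(counts, columns=cols),
        pd.Series(conditions, index=cols),
    )


def simulate_nb(rng, n, mu, alpha, reps_per_cond, fold=None, frac=0.0):
    """NB counts for a 2-condition design with optional planted fold changes."""
    mu = np.full(n, float(mu)) if np.isscalar(mu) else np.asarray(mu)
    changed = np.zeros(n, dtype=bool)
    changed[: int(frac * n)] = True
    mu_b = np.where(changed, mu * (fold or 1.0), mu)
    def draw(m, k):
        lam = rng.gamma(1 / alpha, np.outer(m, np.ones(k)) * alpha)
        return rng.poisson(lam)
    counts = np.hstack([draw(mu, reps_per_cond), draw(mu_b, reps_per_cond)])
    return make_matrix(counts, reps_per_cond, reps_per_cond), changed


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        m = make_matrix(np.tile([[10], [20], [30]], (1, 4)), 2, 2)
        np.testing.assert_allclose(size_factors(m).to_numpy(), 1.0)

    def test_doubled_column_ratio(self):
        base = np.array([[10], [20], [30], [7]])
        m = make_matrix(np.hstack([base, 2 * base]), 1, 1)
        sf = size_factors(m).to_numpy()
        assert sf[1] / sf[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_matches_direct_median_of_ratios(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(200, 4)) + 1
        m = make_matrix(counts, 2, 2)
        log_geo = np.mean(np.log(counts), axis=1)
        expected = np.exp(
            np.median(np.log(counts) - log_geo[:, None], axis=0)
        )
        np.testing.assert_allclose(size_factors(m).to_numpy(), expected, atol=1e-12)

    def test_global_rescaling_leaves_relative_factors(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(30, size=(100, 3)) + 1
        m1 = make_matrix(counts, 2, 1)
        m2 = make_matrix(counts * 7, 2, 1)
        np.testing.assert_allclose(
            size_factors(m1).to_numpy() / size_factors(m2).to_numpy(),
            (size_factors(m1).to_numpy() / size_factors(m2).to_numpy())[0],
        )

    def test_fallback_to_library_size(self):
        counts = np.array([[0, 5], [3, 0]])
        m = make_matrix(counts, 1, 1)
        with pytest.warns(RuntimeWarning):
            sf = size_factors(m)
        assert (sf > 0).all()


class TestEstimateDispersion:
    def test_poisson_counts_give_small_alpha(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=(2000, 6))
        m = make_matrix(counts, 3, 3)
        alpha = estimate_dispersion(m, size_factors(m))
        assert np.median(alpha) <= 0.05

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(3)
        m, _ = simulate_nb(rng, 2000, 100, alpha=0.2, reps_per_cond=3)
        alpha = estimate_dispersion(m, size_factors(m))
        assert 0.1 <= np.median(alpha) <= 0.3

    def test_zero_variance_feature_gets_trend_value(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(50, size=(50, 4))
        counts[0] = [40, 40, 40, 40]
        m = make_matrix(counts, 2, 2)
        alpha = estimate_dispersion(m, size_factors(m))
        # moment estimate is clipped to 0 < trend, so the floor assigns trend
        others = alpha.iloc[1:]
        assert alpha.iloc[0] > 0
        assert alpha.iloc[0] <= others.max() + 1e-9


class TestNBWaldTest:
    def test_identical_groups_null_feature(self):
        m = make_matrix([[5, 7, 5, 7], [9, 9, 9, 9]], 2, 2)
        res = nb_wald_test(m, "A", "B")
        assert res[1].log2fc == pytest.approx(0.0, abs=1e-9)
        assert res[1].p == pytest.approx(1.0)

    def test_all_zero_feature(self):
        m = make_matrix([[0, 0, 0, 0], [10, 12, 9, 11]], 2, 2)
        res = nb_wald_test(m, "A", "B")
        assert (res[0].p, res[0].log2fc) == (1.0, 0.0)

    def test_requires_two_replicates(self):
        m = make_matrix([[1, 2, 3]], conditions=["A", "A", "B"])
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_test(m, "A", "B")

    def test_planted_fold_changes_recovered_with_right_sign(self):
        rng = np.random.default_rng(5)
        m, changed = simulate_nb(
            rng, 2000, 100, alpha=0.1, reps_per_cond=3, fold=4.0, frac=0.1
        )
        res = nb_wald_test(m, "A", "B")
        l2fc = np.array([r.log2fc for r in res])
        assert (l2fc[changed] > 0).mean() >= 0.95

    def test_swapping_conditions_negates_log2fc(self):
        rng = np.random.default_rng(6)
        m, _ = simulate_nb(rng, 50, 80, alpha=0.05, reps_per_cond=3, fold=3.0, frac=0.3)
        ab = nb_wald_test(m, "A", "B")
        ba = nb_wald_test(m, "B", "A")
        np.testing.assert_allclose(
            [r.log2fc for r in ab], [-r.log2fc for r in ba], atol=1e-8
        )

    def test_agrees_with_pydeseq2_on_effect_direction(self):
        """Independent cross-check: log2fc should track DESeq2's closely."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(7)
        m, changed = simulate_nb(
            rng, 300, 100, alpha=0.1, reps_per_cond=3, fold=4.0, frac=0.2
        )
        res = nb_wald_test(m, "A", "B")
        meta = pd.DataFrame({"condition": m.condition})
        dds = DeseqDataSet(
            counts=m.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        ours = np.array([r.log2fc for r in res])
        theirs = ds.results_df["log2FoldChange"].to_numpy()
        assert np.corrcoef(ours, theirs)[0, 1] > 0.95
        assert (np.sign(ours[changed]) == np.sign(theirs[changed])).mean() > 0.95


class TestBHFDR:
    def test_all_tied_pvalues(self):
        np.testing.assert_allclose(bh_fdr([0.01] * 10), 0.01)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])


class TestClassify:
    @pytest.mark.parametrize(
        "p,fc,expected",
        [(0.05, 3.0, "UP"), (0.5, 8.0, "UN"), (0.05, 1.5, "UN"), (0.05, 1 / 3, "DN")],
    )
    def test_binding_style_cuts(self, p, fc, expected):
        res = [NBTestResult("x", 100.0, np.log2(fc), p)]
        out = classify(res, fdr_cut=0.1, fc_cut=2.0, fc_scale="linear")
        assert out[0].class_ == expected

    @pytest.mark.parametrize(
        "p,l2fc,expected", [(0.01, 0.7, "UP"), (0.01, 0.3, "UN"), (0.01, -0.7, "DN")]
    )
    def test_expression_style_cuts(self, p, l2fc, expected):
        res = [NBTestResult("x", 100.0, l2fc, p)]
        out = classify(res, fdr_cut=0.05, fc_cut=0.5, fc_scale="log2")
        assert out[0].class_ == expected

    def test_pure_function_of_inputs(self):
        res = [NBTestResult("a", 10.0, 1.5, 0.001), NBTestResult("b", 10.0, -0.2, 0.8)]
        out1 = classify(res, 0.1, 2.0)
        out2 = classify(res, 0.1, 2.0)
        assert [r.class_ for r in out1] == [r.class_ for r in out2] == ["UP", "UN"]


class TestKS:
    def test_identical_samples(self):
        r = ks_test_two_sample([1, 2, 3], [1, 2, 3])
        assert r.d == 0.0 and r.p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert ks_test_two_sample([1, 2, 3], [4, 5, 6]).d == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_step_function_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=23)
        y = rng.normal(0.5, size=31)
        d = ks_test_two_sample(x, y).d
        grid = np.concatenate([x, y])
        oracle = max(
            abs(np.mean(x <= g) - np.mean(y <= g)) for g in grid
        )
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_asymptotic_p_close_to_permutation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        y = rng.normal(0.7, size=20)
        res = ks_test_two_sample(x, y)
        pool = np.concatenate([x, y])
        n_perm = 20_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            d = ks_test_two_sample(perm[:20], perm[20:]).d
            count += d >= res.d - 1e-12
        assert abs(res.p - count / n_perm) < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_test_two_sample([], [1.0])


class TestAnovaBonferroni:
    def test_identical_constant_groups(self):
        r = anova_bonferroni([[2, 2, 2], [2, 2, 2]])
        assert r["f"] == 0.0 and r["p"] == 1.0

    def test_pairwise_adjustment_is_raw_times_pairs(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(size=10), rng.normal(size=10), rng.normal(1, size=10)]
        r = anova_bonferroni(groups)
        k = 3
        for (i, j), adj in r["pairwise"].items():
            raw = stats.ttest_ind(groups[i], groups[j]).pvalue
            assert adj == pytest.approx(min(1.0, raw * k))

    def test_detects_separated_groups(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(50):
            a, b = rng.normal(size=50), rng.normal(2, size=50)
            if anova_bonferroni([a, b])["p"] < 0.001:
                hits += 1
        assert hits >= 49

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0, 2.0]])
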