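from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from moralchoice import stats


def _long(mat, factors):
    """Subjects x cells matrix -> long frame (cells in lexicographic order)."""
    n, _ = mat.shape
    levels = list(product(*[["a", "b"]] * len(factors)))
    rows = []
    for i in range(n):
        for j, cell in enumerate(levels):
            row = {"subject_id": i, "y": mat[i, j]}
            row.update(dict(zip(factors, cell)))
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_one_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(12, 2))
        res = stats.rm_anova(_long(mat, ["f"]), "y", ["f"])
        t, _ = sps.ttest_rel(mat[:, 1], mat[:, 0])
        eff = res.effect("f")
        assert eff["F"] == pytest.approx(t**2, rel=1e-10)
        assert (eff["df1"], eff["df2"]) == (1, 11)

    def test_hand_decomposed_2x2_fixture(self):
        """4-subject 2x2 fixture against a manual SS decomposition."""
        # cells ordered (a,a) (a,b) (b,a) (b,b)
        mat = np.array(
            [
                [3.0, 5.0, 4.0, 8.0],
                [2.0, 4.0, 5.0, 7.0],
                [4.0, 6.0, 3.0, 9.0],
                [3.0, 5.0, 4.0, 8.0],
            ]
        )
        res = stats.rm_anova(_long(mat, ["A", "B"]), "y", ["A", "B"])
        n = 4
        # manual orthogonal-contrast decomposition
        wA = np.array([-1, -1, 1, 1])
        wB = np.array([-1, 1, -1, 1])
        wAB = wA * wB
        for name, w in [("A", wA), ("B", wB), ("A x B", wAB)]:
            theta_i = mat @ w / 4.0
            ss_eff = n * 4 * theta_i.mean() ** 2
            ss_err = 4 * np.sum((theta_i - theta_i.mean()) ** 2)
            eff = res.effect(name)
            assert eff["ss_effect"] == pytest.approx(ss_eff, rel=1e-12)
            assert eff["ss_error"] == pytest.approx(ss_err, rel=1e-12)
        # classical check: SS for main effect A from cell means
        grand = mat.mean()
        mA = [mat[:, :2].mean(), mat[:, 2:].mean()]
        ss_A_classic = n * 2 * sum((m - grand) ** 2 for m in mA)
        assert res.effect("A")["ss_effect"] == pytest.approx(ss_A_classic, rel=1e-12)

    def test_partial_eta_squared_identity(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(10, 4))
        res = stats.rm_anova(_long(mat, ["A", "B"]), "y", ["A", "B"])
        for _, row in res.table.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(
                row["ss_effect"] / (row["ss_effect"] + row["ss_error"])
            )
            assert row["partial_eta_sq"] == pytest.approx(
                row["F"] / (row["F"] + row["df2"])
            )

    def test_three_factor_runs(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(8, 8))
        res = stats.rm_anova(_long(mat, ["A", "B", "C"]), "y", ["A", "B", "C"])
        assert len(res.table) == 7  # all non-empty factor subsets

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(400):
            mat = rng.normal(size=(10, 2))
            res = stats.rm_anova(_long(mat, ["f"]), "y", ["f"])
            ps.append(res.effect("f")["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_cell_raises(self):
        df = _long(np.ones((4, 4)), ["A", "B"]).iloc[:-1]
        with pytest.raises(ValueError):
            stats.rm_anova(df, "y", ["A", "B"])

    def test_simple_effect_matches_subset_t(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(9, 4))
        df = _long(mat, ["A", "B"])
        eff = stats.simple_effect(df, "y", "A", within=("B", "a"))
        sub = df[df["B"] == "a"].pivot(index="subject_id", columns="A", values="y")
        t, _ = sps.ttest_rel(sub["b"], sub["a"])
        assert eff["F"] == pytest.approx(t**2, rel=1e-10)


class TestFriedman:
    def test_identical_columns_zero(self):
        X = np.tile(np.arange(5)[:, None], (1, 3)).astype(float)
        chi2, df, p = stats.friedman_test(X)
        assert chi2 == 0.0 and df == 2

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        chi2, df, p = stats.friedman_test(X)
        ref = sps.friedmanchisquare(*[X[:, j] for j in range(4)])
        assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exact_permutation_oracle_5x3(self):
        """Statistic recomputed by a brute-force oracle on every within-row
        permutation; the chi-square p approximates the exact permutation p."""
        X = np.array(
            [[1.0, 2.0, 3.0],
             [1.0, 3.0, 2.0],
             [2.0, 1.0, 3.0],
             [1.0, 2.0, 3.0],
             [1.0, 2.0, 3.0]]
        )
        chi2_obs, df, p_obs = stats.friedman_test(X)

        def oracle_stat(mat):
            R = np.apply_along_axis(sps.rankdata, 1, mat)
            n, k = mat.shape
            num = (k - 1) * np.sum((R.sum(0) - n * (k + 1) / 2) ** 2)
            den = np.sum(R**2) - n * k * (k + 1) ** 2 / 4
            return num / den if den else 0.0

        assert chi2_obs == pytest.approx(oracle_stat(X), rel=1e-12)
        perms = list(permutations(range(3)))
        count = total = 0
        for combo in product(perms, repeat=5):
            mat = np.array([X[i, list(pi)] for i, pi in enumerate(combo)])
            count += oracle_stat(mat) >= chi2_obs - 1e-12
            total += 1
        p_exact = count / total
        assert p_obs == pytest.approx(p_exact, abs=0.02)

    def test_two_columns_direction(self):
        # consistent direction yields larger statistic than mixed direction
        consistent = np.column_stack([np.zeros(8), np.ones(8)])
        mixed = consistent.copy()
        mixed[:4] = mixed[:4, ::-1]
        assert (
            stats.friedman_test(consistent)[0] > stats.friedman_test(mixed)[0]
        )

    def test_pairwise_bonferroni(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        tab = stats.pairwise_wilcoxon(X)
        assert len(tab) == 3
        assert (tab["p_adj"] >= tab["p"]).all()
        assert (tab["p_adj"] <= 1.0).all()

    def test_incomplete_rows_raise(self):
        X = np.array([[1.0, 2.0], [np.nan, 1.0]])
        with pytest.raises(ValueError):
            stats.friedman_test(X)


class TestCohenF2:
    def test_half(self):
        assert stats.cohen_f2(0.5) == pytest.approx(1.0)

    def test_zero(self):
        assert stats.cohen_f2(0.0) == 0.0

    def test_inversion(self):
        assert stats.cohen_f2(0.491 / 1.491) == pytest.approx(0.491, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            stats.cohen_f2(1.0)


class TestPower:
    def test_reported_values(self):
        assert stats.regression_posthoc_power(0.491, 7, 46).power == pytest.approx(
            0.910, abs=0.005
        )
        assert stats.regression_posthoc_power(0.379, 7, 46).power == pytest.approx(
            0.808, abs=0.005
        )

    def test_null_equals_alpha(self):
        res = stats.regression_posthoc_power(0.0, 7, 46, alpha=0.05)
        assert res.power == 0.05

    def test_monotone(self):
        p = [stats.regression_posthoc_power(f2, 7, 46).power for f2 in (0.1, 0.3, 0.5)]
        assert p[0] < p[1] < p[2]
        pn = [stats.regression_posthoc_power(0.3, 7, n).power for n in (20, 46, 90)]
        assert pn[0] < pn[1] < pn[2]

    def test_lambda_conventions_coincide(self):
        # f2*N == f2*(df1 + df2 + 1) when df2 = N - df1 - 1
        res = stats.regression_posthoc_power(0.491, 7, 46)
        df1, df2 = res.n_predictors, res.N - res.n_predictors - 1
        assert res.noncentrality == pytest.approx(0.491 * (df1 + df2 + 1))

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            stats.regression_posthoc_power(0.3, 7, 8)

    def test_monte_carlo_cross_check(self):
        mc = stats.simulated_regression_power(0.491, 7, 46, n_sims=40_000, seed=0)
        assert mc == pytest.approx(
            stats.regression_posthoc_power(0.491, 7, 46).power, abs=0.006
        )
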