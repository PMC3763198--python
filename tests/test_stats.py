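"""Inference-layer oracles: closed forms, exhaustive enumerations, and
cross-checks against independent implementations (scipy, pingouin)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sst

from edaflow.errors import ConfigurationError, UndefinedTestError
from edaflow.stats import (
    bonferroni,
    friedman,
    gg_epsilon,
    pearson,
    rm_anova,
    wilcoxon_signed_rank,
)


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 5
        S = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_contrast_attains_lower_bound(self):
        # all variance in a single contrast: the non-sphericity extreme
        k = 4
        c = np.array([1.0, -1.0, 0.0, 0.0])
        S = np.outer(c, c)
        assert gg_epsilon(S) == pytest.approx(1.0 / (k - 1), abs=1e-12)

    def test_matches_eigenvalue_formula_on_random_spd(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(3, 7))
            A = rng.normal(size=(k, k))
            S = A @ A.T
            # independent route: eigenvalues of the double-centred matrix
            P = np.eye(k) - np.ones((k, k)) / k
            lam = np.linalg.eigvalsh(P @ S @ P)
            expected = lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))
            assert gg_epsilon(S) == pytest.approx(expected, rel=1e-10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ConfigurationError):
            gg_epsilon(np.array([[1.0]]))


class TestRmAnova:
    def test_two_levels_equal_squared_paired_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(12, 2))
        res = rm_anova(y)
        t = sst.ttest_rel(y[:, 0], y[:, 1])
        assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_uncorrected == pytest.approx(t.pvalue, rel=1e-10)
        assert res.epsilon_gg == pytest.approx(1.0, abs=1e-12)

    def test_identical_columns_give_zero_f(self):
        y = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova(y)
        assert res.F == 0.0
        assert res.p_uncorrected == 1.0

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        y = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1))
        res = rm_anova(y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 4),
                "level": np.tile(np.arange(4), 10),
                "y": y.ravel(),
            }
        )
        table = pg.rm_anova(
            data=long, dv="y", within="level", subject="subject", correction=True
        )
        assert res.F == pytest.approx(float(table["F"].iloc[0]), rel=1e-6)
        assert res.p_uncorrected == pytest.approx(
            float(table["p_unc"].iloc[0]), rel=1e-6
        )
        assert res.epsilon_gg == pytest.approx(float(table["eps"].iloc[0]), rel=1e-6)
        assert res.p_gg == pytest.approx(float(table["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_null_calibration_under_compound_symmetry(self):
        """Compound-symmetric Gaussian null, n=20, k=4, 2000 replicates:
        the uncorrected p is exactly uniform (KS at alpha = 0.01) and the
        GG correction only ever pushes p upward (conservative).  The
        epsilon estimate carries its known downward finite-sample bias, so
        its mean sits below but near 1 and approaches 1 as n grows."""
        rng = np.random.default_rng(3)
        eps_values, p_unc, p_gg = [], [], []
        for _ in range(2000):
            y = rng.normal(size=(20, 4)) + rng.normal(size=(20, 1))
            res = rm_anova(y)
            eps_values.append(res.epsilon_gg)
            p_unc.append(res.p_uncorrected)
            p_gg.append(res.p_gg)
        assert 0.80 < np.mean(eps_values) <= 1.0
        ks = sst.kstest(p_unc, "uniform")
        assert ks.pvalue > 0.01
        # GG-corrected test stays near-nominal, never anti-conservative
        rate = np.mean(np.asarray(p_gg) < 0.05)
        assert 0.02 <= rate <= 0.065
        # bias vanishes with sample size
        big = [
            rm_anova(rng.normal(size=(200, 4)) + rng.normal(size=(200, 1))).epsilon_gg
            for _ in range(200)
        ]
        assert np.mean(big) > 0.95

    def test_incomplete_cells_rejected(self):
        y = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(UndefinedTestError, match="missing"):
            rm_anova(y)


def friedman_permutation_oracle(y: np.ndarray) -> tuple[float, float]:
    """Brute-force Friedman: statistic plus exact permutation p value by
    enumerating every within-row rank assignment."""
    n, k = y.shape
    ranks = np.apply_along_axis(sst.rankdata, 1, y)
    centre = n * (k + 1) / 2.0
    denom = float(np.sum(ranks**2)) - n * k * (k + 1) ** 2 / 4.0
    dev2 = float(np.sum((ranks.sum(axis=0) - centre) ** 2))
    stat = (k - 1) * dev2 / denom
    count = total = 0
    for rows in itertools.product(
        *[sorted(set(itertools.permutations(r))) for r in ranks]
    ):
        d2 = float(np.sum((np.sum(rows, axis=0) - centre) ** 2))
        total += 1
        if d2 >= dev2 - 1e-9:
            count += 1
    return stat, count / total


class TestFriedman:
    def test_perfect_concordance_closed_form(self):
        # all rows identically ordered, no ties: chi2 = n(k-1)
        y = np.tile(np.array([1.0, 2.0, 3.0]), (6, 1))
        y += np.arange(6)[:, None]  # distinct rows, same ordering
        res = friedman(y, method="approx")
        assert res.chi2 == pytest.approx(12.0)
        assert res.df == 2

    def test_constant_matrix_gives_zero(self):
        res = friedman(np.full((5, 3), 2.0))
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_statistic_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(9, 4))
        res = friedman(y, method="approx")
        ref = sst.friedmanchisquare(*y.T)
        assert res.chi2 == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(5, 3))
        res = friedman(y, method="exact")
        stat, p_exact = friedman_permutation_oracle(y)
        assert res.chi2 == pytest.approx(stat, rel=1e-10)
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_exact_p_with_ties_matches_oracle(self):
        y = np.array(
            [[1.0, 1.0, 2.0], [2.0, 1.0, 1.0], [3.0, 2.0, 2.0],
             [1.0, 2.0, 3.0], [2.0, 2.0, 2.0]]
        )
        res = friedman(y, method="exact")
        stat, p_exact = friedman_permutation_oracle(y)
        assert res.chi2 == pytest.approx(stat, rel=1e-10)
        assert res.p == pytest.approx(p_exact, abs=1e-12)


class TestWilcoxon:
    def test_identical_sequences_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank(x, x)

    def test_five_positive_differences_exact_one_sided(self):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        res = wilcoxon_signed_rank(x, y, method="exact", alternative="greater")
        assert res.T == 0.0  # negative-rank sum is empty
        assert res.p == pytest.approx(1.0 / 32.0)

    def test_exact_two_sided_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = wilcoxon_signed_rank(x, y, method="exact")
        ref = sst.wilcoxon(x, y, method="exact")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.T == pytest.approx(ref.statistic)

    def test_approx_z_matches_scipy(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = rng.normal(loc=0.3, size=30)
        res = wilcoxon_signed_rank(x, y, method="approx")
        ref = sst.wilcoxon(x, y, method="approx", correction=True)
        assert abs(res.z) == pytest.approx(abs(ref.zstatistic), rel=1e-9)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_effect_size_sign_follows_direction(self):
        x = np.arange(1.0, 11.0)
        res_up = wilcoxon_signed_rank(x + 1.0, x)
        res_down = wilcoxon_signed_rank(x - 1.0, x)
        assert res_up.r > 0
        assert res_down.r < 0

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=6,
            max_size=25,
        ).filter(lambda v: len(set(v)) > 1)
    )
    def test_effect_size_bounded(self, diffs):
        x = np.asarray(diffs)
        y = np.zeros_like(x)
        if np.all(x == 0):
            return
        res = wilcoxon_signed_rank(x, y, method="approx")
        assert abs(res.r) <= 1.0 + 1e-12

    def test_bonferroni_field(self):
        x = np.arange(1.0, 9.0)
        res = wilcoxon_signed_rank(x + 1.0, x, m_comparisons=3)
        assert res.p_bonferroni == pytest.approx(min(1.0, 3 * res.p))


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        assert abs(pearson(x, y).r) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedTestError):
            pearson(np.ones(10), np.arange(10.0))


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.06, 0.09])
        assert bonferroni([0.5]) == [0.5]

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=20)
        adj = bonferroni(p)
        assert all(a >= b for a, b in zip(adj, p))
        assert all(a <= 1.0 for a in adj)
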