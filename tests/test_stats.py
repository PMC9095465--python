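"""Cohort-level inference: Kruskal-Wallis, chi-square, ANCOVA with
post-hoc contrasts, partial correlation, BH-FDR, Cohen's d."""

import numpy as np
import pytest
from scipy import stats as sps

from fcpipe import (
    ancova_group_effect,
    chi_square_independence,
    cohens_d,
    fdr_bh,
    kruskal_wallis,
    partial_correlation,
)
from oracles import bh_by_hand, kruskal_by_hand, partial_corr_by_hand


class TestKruskalWallis:
    def test_identical_multisets_give_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        h, p = kruskal_wallis([g, g.copy(), g.copy()])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_maximal_separation_hand_value(self):
        h, p = kruskal_wallis(
            [np.array([1, 2, 3.0]), np.array([4, 5, 6.0]), np.array([7, 8, 9.0])]
        )
        assert h == pytest.approx(7.2)

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            samples = [rng.integers(0, 8, size=rng.integers(4, 9)).astype(float)
                       for _ in range(3)]
            h, _ = kruskal_wallis(samples)
            assert h == pytest.approx(kruskal_by_hand(samples), abs=1e-10)

    def test_all_identical_degenerate(self):
        h, p = kruskal_wallis([np.ones(4), np.ones(5)])
        assert (h, p) == (0.0, 1.0)


class TestChiSquare:
    def test_identical_columns_force_zero(self):
        # 35 men / 39 women in each of three groups
        chi2, p = chi_square_independence([[35, 35, 35], [39, 39, 39]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        chi2, _ = chi_square_independence([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_doubling_counts_doubles_statistic(self):
        t = np.array([[12, 5], [7, 9]])
        c1, _ = chi_square_independence(t)
        c2, _ = chi_square_independence(2 * t)
        assert c2 == pytest.approx(2 * c1)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[0, 0], [3, 4]])


class TestAncova:
    def test_reduces_to_anova_without_covariate_signal(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=90)
        grp = np.repeat(["a", "b", "c"], 30)
        res = ancova_group_effect(y, grp, None)
        f_ref, p_ref = sps.f_oneway(y[:30], y[30:60], y[60:])
        assert res.f_stat == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)
        assert res.df_between == 2
        assert res.df_residual == 87

    def test_constant_response_is_null(self):
        grp = np.repeat(["a", "b"], 10)
        covs = np.random.default_rng(2).normal(size=(20, 2))
        res = ancova_group_effect(np.full(20, 3.0), grp, covs)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0
        assert all(d == 0.0 for _, _, d in res.posthoc)

    def test_covariate_adjustment_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 60
        grp = np.repeat(["a", "b", "c"], 20)
        age = rng.uniform(20, 60, n)
        y = 0.05 * age + rng.normal(size=n) + (grp == "c") * 0.8
        res = ancova_group_effect(y, grp, age.reshape(-1, 1))
        x_full = np.column_stack(
            [np.ones(n), (grp == "b").astype(float), (grp == "c").astype(float), age]
        )
        x_red = np.column_stack([np.ones(n), age])
        full = sm.OLS(y, x_full).fit()
        red = sm.OLS(y, x_red).fit()
        f_ref = ((red.ssr - full.ssr) / 2) / (full.ssr / (n - 4))
        assert res.f_stat == pytest.approx(f_ref)

    def test_planted_shift_recovers_unit_effect_size(self):
        """1-sd group shift at n=74/group: mean post-hoc |d| near 1."""
        ds = []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            y = np.concatenate([rng.normal(0, 1, 74), rng.normal(1, 1, 74)])
            grp = np.repeat(["x", "z"], 74)
            covs = np.column_stack(
                [rng.normal(size=148), rng.integers(0, 2, 148).astype(float)]
            )
            ds.append(abs(ancova_group_effect(y, grp, covs).posthoc[0][2]))
        assert 0.7 <= np.mean(ds) <= 1.3

    def test_null_type_one_error_calibrated(self):
        """Rejection rate at alpha=0.05 under the null, 200 simulations."""
        rej = 0
        for seed in range(200):
            rng = np.random.default_rng(40_000 + seed)
            y = rng.normal(size=90)
            grp = np.repeat(["a", "b", "c"], 30)
            covs = np.column_stack(
                [rng.normal(size=90), rng.integers(0, 2, 90).astype(float)]
            )
            if ancova_group_effect(y, grp, covs).p_value < 0.05:
                rej += 1
        assert 0.02 <= rej / 200 <= 0.09

    def test_collinear_design_errors(self):
        grp = np.repeat(["a", "b"], 10)
        covs = np.column_stack([(grp == "a").astype(float)])  # aliases the dummy
        with pytest.raises(ValueError, match="collinear"):
            ancova_group_effect(np.random.default_rng(0).normal(size=20), grp, covs)


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        res = partial_correlation(x, y, None)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert res.df == 38

    def test_perfect_dependence(self):
        x = np.linspace(0, 1, 20)
        res = partial_correlation(x, x.copy(), None)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_hand_worked_small_dataset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        cov = np.array([[0.5], [1.5], [1.0], [2.5], [2.0], [3.0]])
        res = partial_correlation(x, y, cov)
        assert res.r == pytest.approx(partial_corr_by_hand(x, y, cov), abs=1e-12)
        assert res.df == 3

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=50),
                "y": rng.normal(size=50),
                "c1": rng.normal(size=50),
                "c2": rng.normal(size=50),
            }
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = partial_correlation(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["c1", "c2"]].to_numpy()
        )
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_constant_residuals_error(self):
        cov = np.arange(10.0).reshape(-1, 1)
        x = 2.0 * cov[:, 0] + 1.0  # fully explained by the covariate
        y = np.random.default_rng(6).normal(size=10)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(x, y, cov)


class TestFdrBh:
    def test_step_up_rejects_all_four(self):
        reject, adj = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()

    def test_all_ones(self):
        reject, adj = fdr_bh(np.ones(5), q=0.05)
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_single_p_identity(self):
        reject, adj = fdr_bh(np.array([0.04]), q=0.05)
        assert reject[0]
        assert adj[0] == pytest.approx(0.04)

    def test_matches_hand_step_up(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = rng.uniform(size=12)
            reject, _ = fdr_bh(p, q=0.1)
            assert np.array_equal(reject, bh_by_hand(p, 0.1))

    def test_never_rejects_more_than_uncorrected(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        reject, _ = fdr_bh(p, q=0.05)
        assert reject.sum() <= (p <= 0.05).sum()


class TestCohensD:
    def test_equal_means(self):
        assert cohens_d(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == 0.0

    def test_hand_computed(self):
        # a=(0,2), b=(1,3): means 1 vs 2, pooled sd sqrt(2) -> d = -0.7071
        assert cohens_d(np.array([0.0, 2.0]), np.array([1.0, 3.0])) == pytest.approx(
            -1 / np.sqrt(2)
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=20), rng.normal(1, 1, size=25)
        assert cohens_d(3.0 * a, 3.0 * b) == pytest.approx(cohens_d(a, b))

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(np.ones(3), np.ones(4))
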