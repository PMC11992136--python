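"""Group inference: ANOVA, effect sizes, Tukey-Kramer, GLMs, chi-squared."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from restingnorm.stats import (
    anova_from_summary,
    chi_square_independence,
    cohens_d,
    fit_glm,
    one_way_anova,
    partial_eta_sq,
    tukey_hsd,
)


def _exact_moment_sample(mean, sd, n, seed=0):
    """Sample with exactly the requested mean and (ddof=1) SD."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestOneWayAnova:
    def test_identical_groups_zero_F(self):
        v = np.tile(np.arange(5.0), 3)
        g = np.repeat(["a", "b", "c"], 5)
        res = one_way_anova(v, g)
        assert res.F == pytest.approx(0.0)
        assert res.eta_p_sq == pytest.approx(0.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(90)
        g = np.repeat(["a", "b", "c"], 30)
        v[g == "b"] += 0.5
        res = one_way_anova(v, g)
        ref = sst.f_oneway(v[g == "a"], v[g == "b"], v[g == "c"])
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(20), rng.standard_normal(25) + 0.3
        res = one_way_anova(np.concatenate([a, b]),
                            np.repeat(["a", "b"], [20, 25]))
        t = sst.ttest_ind(a, b).statistic
        assert res.F == pytest.approx(t**2, abs=1e-10)

    def test_null_p_values_uniform(self):
        """Under the null the ANOVA p-value is Uniform(0,1)."""
        rng = np.random.default_rng(3)
        groups = np.repeat(["CTRL", "DEL", "DUP"], [256, 66, 43])
        pvals = [
            one_way_anova(rng.standard_normal(365), groups).p
            for _ in range(500)
        ]
        assert sst.kstest(pvals, "uniform").pvalue > 0.01

    def test_eta_identity(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(60)
        g = np.repeat(["a", "b", "c"], 20)
        res = one_way_anova(v, g)
        assert res.eta_p_sq == pytest.approx(
            res.ss_between / (res.ss_between + res.ss_within), abs=1e-12
        )
        assert res.eta_p_sq == pytest.approx(
            partial_eta_sq(res.F, res.df1, res.df2), abs=1e-12
        )


class TestSummaryAnova:
    def test_duplicated_group_zero_F(self):
        res = anova_from_summary([2.0, 2.0], [1.0, 1.0], [10, 10])
        assert res.F == 0.0

    def test_agrees_with_raw_anova_on_exact_moments(self):
        means, sds, ns = [1.0, 1.5, 0.8], [0.5, 0.7, 0.6], [20, 25, 30]
        vals = np.concatenate(
            [_exact_moment_sample(m, s, n, seed=i)
             for i, (m, s, n) in enumerate(zip(means, sds, ns))]
        )
        groups = np.repeat(["a", "b", "c"], ns)
        raw = one_way_anova(vals, groups)
        summ = anova_from_summary(means, sds, ns)
        assert summ.F == pytest.approx(raw.F, abs=1e-9)
        assert summ.eta_p_sq == pytest.approx(raw.eta_p_sq, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([1.0, 2.0], [1.0, 1.0], [1, 10])


class TestPartialEta:
    def test_zero_F(self):
        assert partial_eta_sq(0.0, 2, 100) == 0.0

    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [(74.4, 2, 193, 0.435), (11.11, 2, 362, 0.058)],
    )
    def test_published_values(self, F, df1, df2, expected):
        assert round(partial_eta_sq(F, df1, df2), 3) == expected


class TestCohensD:
    def test_identical_groups(self):
        x = np.arange(10.0)
        assert cohens_d(x, x) == 0.0

    def test_unit_difference_exact_moments(self):
        a = _exact_moment_sample(1.0, 1.0, 500, seed=3)
        b = _exact_moment_sample(0.0, 1.0, 500, seed=4)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_injected_shift_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(200) + 0.5
        b = rng.standard_normal(200)
        assert abs(cohens_d(a, b) - 0.5) <= 0.15


class TestTukey:
    def test_identical_groups_null(self):
        x = np.tile(np.arange(20.0), 3)
        g = np.repeat(["a", "b", "c"], 20)
        for rec in tukey_hsd(x, g):
            assert rec.p_tukey > 0.99
            assert rec.ci_low <= 0.0 <= rec.ci_high

    def test_shifted_group_detected(self):
        # a and b share exact moments (true null); c is shifted by 5 SD
        v = np.concatenate(
            [_exact_moment_sample(0.0, 1.0, 50, seed=6),
             _exact_moment_sample(0.0, 1.0, 50, seed=7),
             _exact_moment_sample(5.0, 1.0, 50, seed=8)]
        )
        g = np.repeat(["a", "b", "c"], 50)
        recs = {r.pair: r for r in tukey_hsd(v, g)}
        assert recs[("a", "c")].p_tukey < 1e-6
        assert recs[("b", "c")].p_tukey < 1e-6
        assert recs[("a", "b")].p_tukey > 0.5

    def test_matches_permutation_max_range_null(self):
        """Studentized-range p-values agree with a seeded brute-force
        permutation of the max standardized pairwise difference."""
        rng = np.random.default_rng(7)
        v = np.concatenate(
            [rng.standard_normal(8), rng.standard_normal(8) + 1.2,
             rng.standard_normal(8)]
        )
        g = np.repeat(["a", "b", "c"], 8)
        recs = {r.pair: r for r in tukey_hsd(v, g)}

        def q_stats(values):
            groups = values.reshape(3, 8)
            means = groups.mean(axis=1)
            msw = groups.var(ddof=1, axis=1).mean()
            se = np.sqrt(msw / 8)
            return np.abs(means[:, None] - means[None, :]) / se

        obs = q_stats(v)
        count = np.zeros((3, 3))
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(v)
            count += (q_stats(perm).max() >= obs - 1e-12)
        p_perm = count / n_perm
        for (i, gi), (j, gj) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")),
                                 ((1, "b"), (2, "c"))]:
            assert abs(recs[(gi, gj)].p_tukey - p_perm[i, j]) < 0.05

    def test_not_below_unadjusted_pairwise_p(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal(60)
        g = np.repeat(["a", "b", "c"], 20)
        v[g == "b"] += 0.8
        recs = tukey_hsd(v, g)
        for rec in recs:
            a = v[g == rec.pair[0]]
            b = v[g == rec.pair[1]]
            p_t = sst.ttest_ind(a, b).pvalue
            assert rec.p_tukey >= p_t - 0.02


class TestChiSquare:
    def test_published_sex_table(self):
        x2, df, p = chi_square_independence([[40, 26], [25, 18], [140, 116]])
        assert round(x2, 2) == 0.82
        assert df == 2

    def test_proportional_table_zero(self):
        x2, _, _ = chi_square_independence([[10, 20], [20, 40]])
        assert x2 == pytest.approx(0.0)

    def test_diagonal_table(self):
        x2, df, _ = chi_square_independence([[10, 0], [0, 10]])
        assert x2 == pytest.approx(20.0)
        assert df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 5]])


class TestGlm:
    def _cohort(self, n=120, seed=9, groups=("CTRL", "DEL", "DUP")):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "group": rng.choice(groups, n),
                "sex": rng.choice(["M", "F"], n),
                "age": rng.uniform(3, 17, n),
            }
        )

    def test_noiseless_coefficients_exact(self):
        cohort = self._cohort()
        status = (cohort["group"] != "CTRL").astype(float)
        y = 0.5 - 0.8 * status + 0.1 * cohort["age"]
        table = fit_glm(1, y.to_numpy(), cohort)
        coef = dict(zip(table["term"], table["beta"]))
        assert coef["Intercept"] == pytest.approx(0.5, abs=1e-9)
        assert coef["Status"] == pytest.approx(-0.8, abs=1e-9)
        assert coef["Age"] == pytest.approx(0.1, abs=1e-9)
        assert coef["Status:Sex"] == pytest.approx(0.0, abs=1e-9)

    def test_dosage_model_expands_indicators(self):
        cohort = self._cohort()
        y = np.zeros(len(cohort))
        table = fit_glm(2, y, cohort)
        assert set(table["term"]) == {
            "Intercept", "DEL", "DUP", "Sex", "Age",
            "DEL:Sex", "DUP:Sex", "Age:DEL", "Age:DUP",
        }

    def test_coverage_simulation(self):
        """95% CIs cover the true coefficients at near-nominal rate."""
        hits = np.zeros(6)
        n_rep = 200
        beta = {"Intercept": 0.2, "Status": -0.5, "Sex": 0.3, "Age": 0.05,
                "Status:Sex": 0.4, "Age:Status": -0.08}
        for rep in range(n_rep):
            cohort = self._cohort(n=365, seed=1000 + rep)
            rng = np.random.default_rng(2000 + rep)
            status = (cohort["group"] != "CTRL").astype(float).to_numpy()
            sex = (cohort["sex"] == "M").astype(float).to_numpy()
            age = cohort["age"].to_numpy()
            y = (
                beta["Intercept"] + beta["Status"] * status + beta["Sex"] * sex
                + beta["Age"] * age + beta["Status:Sex"] * status * sex
                + beta["Age:Status"] * age * status + rng.standard_normal(365)
            )
            table = fit_glm(1, y, cohort)
            for i, (_, row) in enumerate(table.iterrows()):
                true = beta[row["term"]]
                half = 1.96 * row["se"]
                hits[i] += (row["beta"] - half <= true <= row["beta"] + half)
        assert np.all(hits / n_rep >= 0.93)

    def test_missing_group_rank_deficient(self):
        cohort = self._cohort(groups=("CTRL", "DEL"))
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_glm(2, np.zeros(len(cohort)), cohort)
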