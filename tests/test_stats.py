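"""Statistics chain against brute-force oracles and simulation recovery."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dtialps.stats import (
    ancova_group,
    group_compare,
    multiple_regression,
    pearson,
    report_markdown,
)
from dtialps.synthdata import CohortSpec, generate_cohort


def nested_rss_f(y, X_full, X_reduced):
    """Brute-force partial F via normal-equations fits of nested models."""

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return r @ r

    rss_f, rss_r = rss(X_full), rss(X_reduced)
    df_resid = len(y) - X_full.shape[1]
    return ((rss_r - rss_f) / 1.0) / (rss_f / df_resid)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = pearson(x, y)
        # oracle: direct covariance / SD computation
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.r == pytest.approx(r, abs=1e-12)
        t = r * np.sqrt(8 / (1 - r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 8), rel=1e-9)

    def test_pairwise_deletion_counts_complete_pairs(self):
        x = np.array([1, 2, 3, np.nan, 5, 6.0])
        y = np.array([2, 4, np.nan, 8, 10, 11.0])
        assert pearson(x, y).n == 4

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson(np.ones(5), np.arange(5.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestAncova:
    def test_pure_group_effect_without_noise_flagged_as_exact(self, rng):
        age = np.concatenate([rng.uniform(20, 80, 20)] * 2)
        group = np.array(["A"] * 20 + ["B"] * 20)
        dep = 1.0 + 0.01 * age + 0.5 * (group == "A")
        res = ancova_group(dep, group, age)
        assert np.isinf(res.f_group) and res.p_group == 0.0

    def test_large_effect_with_tiny_noise_is_significant(self, rng):
        age = np.concatenate([rng.uniform(20, 80, 20)] * 2)
        group = np.array(["A"] * 20 + ["B"] * 20)
        dep = 1.0 + 0.01 * age + 0.5 * (group == "A") + rng.normal(0, 1e-3, 40)
        assert ancova_group(dep, group, age).p_group < 1e-10

    def test_identical_group_distributions_give_zero_f(self):
        age = np.tile(np.linspace(20, 80, 15), 2)
        dep = np.tile(np.linspace(1, 2, 15), 2)
        group = np.array(["A"] * 15 + ["B"] * 15)
        assert ancova_group(dep, group, age).f_group == pytest.approx(0.0, abs=1e-18)

    def test_partial_f_matches_nested_rss_oracle(self):
        table, _ = generate_cohort(CohortSpec(seed=42))
        res = ancova_group(table["alps_mean"], table["group"].to_numpy(), table["age"])
        y = table["alps_mean"].to_numpy()
        g = (table["group"].to_numpy() == "TBI").astype(float)
        X_full = np.column_stack([np.ones(len(y)), g, table["age"]])
        f_group = nested_rss_f(y, X_full, X_full[:, [0, 2]])
        f_age = nested_rss_f(y, X_full, X_full[:, [0, 1]])
        assert res.f_group == pytest.approx(f_group, rel=1e-10)
        assert res.covariate_tests["age"][0] == pytest.approx(f_age, rel=1e-10)
        assert res.df == (1, len(y) - 3)

    def test_adjusted_means_at_covariate_grand_mean(self, rng):
        age = rng.uniform(20, 80, 50)
        group = np.array(["A"] * 25 + ["B"] * 25)
        dep = 2.0 - 0.01 * age + 0.3 * (group == "A") + rng.normal(0, 0.05, 50)
        res = ancova_group(dep, group, age)
        diff = res.adjusted_group_means["A"] - res.adjusted_group_means["B"]
        assert diff == pytest.approx(0.3, abs=0.05)

    def test_collinear_covariate_rejected(self):
        group = np.array(["A"] * 10 + ["B"] * 10)
        dep = np.arange(20.0)
        cov = pd.DataFrame({"age": (group == "A").astype(float)})  # aliases group
        with pytest.raises(ValueError, match="singular"):
            ancova_group(dep, group, cov)


class TestRegression:
    def test_single_predictor_standardized_coef_equals_pearson_r(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        reg = multiple_regression(y, pd.DataFrame({"x": x}))
        assert reg.coefficients.loc["x", "b_std"] == pytest.approx(pearson(x, y).r, abs=1e-12)

    def test_exact_linear_combination_r2_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        y = 1 + 2 * X["a"] - 3 * X["b"] + 0.5 * X["c"]
        assert multiple_regression(y.to_numpy(), X).r_squared == pytest.approx(1.0)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = 1 + 2 * X["a"] - 3 * X["b"] + rng.normal(size=20)
        reg = multiple_regression(y.to_numpy(), X)
        Xd = np.column_stack([np.ones(20), X.to_numpy()])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y.to_numpy())
        np.testing.assert_allclose(reg.coefficients["b_raw"], beta[1:], rtol=1e-10)

    def test_standardized_unstandardized_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] - X["c"] + rng.normal(size=40)
        reg = multiple_regression(y.to_numpy(), X)
        for c in X.columns:
            expected = reg.coefficients.loc[c, "b_raw"] * X[c].std(ddof=1) / y.std(ddof=1)
            assert reg.coefficients.loc[c, "b_std"] == pytest.approx(expected, rel=1e-10)

    def test_partial_residual_slope_equals_raw_coefficient(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] - X["c"] + rng.normal(size=40)
        reg = multiple_regression(y.to_numpy(), X)
        rx, ry = reg.partial_residuals["a"]
        slope = (rx * ry).sum() / (rx * rx).sum()
        assert slope == pytest.approx(reg.coefficients.loc["a", "b_raw"], rel=1e-8)

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            multiple_regression(rng.normal(size=30), X)

    def test_listwise_deletion_n_reported(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=list("ab"))
        y = rng.normal(size=30)
        X.loc[3, "a"] = np.nan
        y[5] = np.nan
        assert multiple_regression(y, X).n == 28


class TestGroupCompare:
    def test_identical_sex_split_gives_zero_chi_square(self):
        table, _ = generate_cohort(CohortSpec(seed=6))
        table["sex"] = np.where(np.arange(len(table)) % 2 == 0, "M", "F")
        # force identical 50/50 split in both groups
        for g in ("TBI", "control"):
            idx = table.index[table.group == g]
            table.loc[idx, "sex"] = ["M", "F"] * (len(idx) // 2) + ["M"] * (len(idx) % 2)
        rep = group_compare(table)
        if "sex_chi2" in rep["demographics"]:
            assert rep["demographics"]["sex_chi2"] < 0.6  # near-zero up to odd counts

    def test_negative_generative_alps_coefficient_recovered(self):
        table, _ = generate_cohort(CohortSpec(seed=9))
        rep = group_compare(table)
        assert rep["nfl_regression"]["coefficients"]["alps_mean"]["b_std"] < 0

    def test_report_reproducible_bit_for_bit(self):
        reports = []
        for _ in range(2):
            table, _ = generate_cohort(CohortSpec(seed=13))
            reports.append(json.dumps(group_compare(table), sort_keys=True))
        assert reports[0] == reports[1]

    def test_missing_columns_named_in_error(self):
        with pytest.raises(ValueError, match="alps_mean"):
            group_compare(pd.DataFrame({"group": ["TBI"], "age": [50], "sex": ["M"]}))

    def test_markdown_report_renders(self):
        table, _ = generate_cohort(CohortSpec(seed=3))
        md = report_markdown(group_compare(table))
        assert "ANCOVA" in md and "alps_mean" in md and "NfL" in md


class TestParameterRecovery:
    def test_adjusted_group_difference_and_ci_coverage(self):
        # 200 simulated cohorts: the mean estimated age-adjusted group
        # difference should sit within 10% of the generative difference,
        # and 95% CIs should cover it at nominal rate
        spec = CohortSpec(seed=0)
        true_diff = spec.group_alps_means["control"] - spec.group_alps_means["TBI"]
        diffs, covered = [], 0
        n_sim = 200
        for s in range(n_sim):
            table, _ = generate_cohort(dataclasses.replace(spec, seed=50_000 + s))
            y = table["alps_mean"].to_numpy()
            g = (table["group"] == "control").astype(float).to_numpy()
            X = np.column_stack([np.ones(len(y)), g, table["age"].to_numpy()])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            s2 = resid @ resid / (len(y) - 3)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            tcrit = sps.t.ppf(0.975, len(y) - 3)
            diffs.append(beta[1])
            covered += abs(beta[1] - true_diff) <= tcrit * se
        assert np.mean(diffs) == pytest.approx(true_diff, rel=0.10)
        assert 0.90 <= covered / n_sim <= 0.99
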