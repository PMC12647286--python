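"""Correlation/FDR, standardized regression, mediation, t-tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alpskit.stats import (
    MEDIATION_PATHS,
    bh_adjust,
    fd_alps_check,
    mediate,
    mediation_battery,
    one_sample_t,
    pearson_matrix_fdr,
    standardized_ols,
    strength_category,
)


class TestBH:
    def test_hand_worked_example(self):
        """p = {0.01, 0.02, 0.03, 0.04} in one family collapse to q = 0.04
        under the step-up minimum."""
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_test_q_equals_p(self):
        np.testing.assert_allclose(bh_adjust([0.031]), [0.031])

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_stepup_and_dominates_p(self, pvals):
        p = np.asarray(pvals)
        # independent hand implementation of the step-up minimum
        m = len(p)
        order = np.argsort(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        got = bh_adjust(p)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert np.all(got >= p - 1e-12)
        assert np.all(np.diff(got[order]) >= -1e-12)


class TestCategories:
    @pytest.mark.parametrize("r, cat", [
        (0.05, "very weak"), (-0.25, "weak"), (0.47, "moderate"),
        (-0.65, "strong"), (0.95, "very strong"),
    ])
    def test_strength_bands(self, r, cat):
        assert strength_category(r) == cat


class TestPearsonMatrix:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df["x"] + 1
        res = pearson_matrix_fdr(df, ["x", "y"])
        assert res["r"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] < 1e-10
        assert res["q"].iloc[0] >= res["p"].iloc[0]

    def test_zero_variance_named_in_error(self):
        df = pd.DataFrame({"x": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            pearson_matrix_fdr(df, ["x", "flat"])

    def test_cross_grid_covers_all_pairs(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = pearson_matrix_fdr(df, ["a", "b"], ["c", "d"])
        assert len(res) == 4
        assert set(res["category"]).issubset(
            {"very weak", "weak", "moderate", "strong", "very strong"})


class TestStandardizedOLS:
    def test_outcome_equal_to_predictor(self, rng):
        n = 200
        df = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        df["y"] = df["x"] * 3.0 + 5.0
        res = standardized_ols(df, "y", ["x", "z"])
        bx = res.set_index("predictor").loc["x"]
        assert bx["beta"] == pytest.approx(1.0, abs=1e-9)
        assert res["vif"].max() < 1.2

    def test_beta_equals_pearson_r_for_simple_regression(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x", "y"])
        df["y"] += 0.5 * df["x"]
        res = standardized_ols(df, "y", ["x"])
        r = df["x"].corr(df["y"])
        assert res["beta"].iloc[0] == pytest.approx(r, abs=1e-12)

    def test_duplicated_predictor_raises_collinearity(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["x2"] = df["x"]
        df["y"] = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinearity"):
            standardized_ols(df, "y", ["x", "x2"])

    def test_planted_coefficients_recovered(self, rng):
        """rCPV = -0.4 ALPS + 0.5 age + noise at n=500: standardized
        estimates within 3 SE of the planted values."""
        n = 500
        alps = rng.normal(size=n)
        age = rng.normal(size=n)
        y = -0.4 * alps + 0.5 * age + rng.normal(scale=0.6, size=n)
        df = pd.DataFrame({"ALPS": alps, "age": age, "rCPV": y})
        res = standardized_ols(df, "rCPV", ["ALPS"], covariates=["age"])
        res = res.set_index("predictor")
        sd_y = y.std(ddof=1)
        for name, planted in (("ALPS", -0.4 / sd_y), ("age", 0.5 / sd_y)):
            row = res.loc[name]
            assert abs(row["beta"] - planted) < 3 * row["se"]

    def test_dummies_not_standardized(self, rng):
        n = 80
        df = pd.DataFrame({"x": rng.normal(size=n),
                           "dx": (rng.random(n) < 0.3).astype(int)})
        df["y"] = df["x"] + 2.0 * df["dx"] + rng.normal(size=n)
        res = standardized_ols(df, "y", ["x"], covariates=["dx"])
        beta_dx = res.set_index("predictor").loc["dx", "beta"]
        assert beta_dx == pytest.approx(2.0 / df["y"].std(ddof=1), abs=0.5)


def _mediation_frame(rng, n=2000, a=0.5, b=0.4, cprime=0.3):
    x = rng.normal(size=n)
    m = a * x + rng.normal(scale=0.8, size=n)
    y = cprime * x + b * m + rng.normal(scale=0.8, size=n)
    return pd.DataFrame({"x": x, "m": m, "y": y, "age": rng.normal(size=n)})


class TestMediation:
    def test_decomposition_identity_exact(self, rng):
        df = _mediation_frame(rng, n=120)
        res = mediate(df, "x", "m", "y", covariates=["age"], n_boot=50, seed=1)
        assert res.acme + res.ade == pytest.approx(res.total, abs=1e-9)
        assert res.acme_ci[0] <= res.acme <= res.acme_ci[1]
        assert res.ade_ci[0] <= res.ade <= res.ade_ci[1]

    def test_null_a_path_gives_null_acme(self, rng):
        n = 500
        x = rng.normal(size=n)
        m = rng.normal(size=n)  # independent of x
        y = 0.5 * m + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        res = mediate(df, "x", "m", "y", covariates=[], n_boot=300, seed=2)
        assert res.acme_ci[0] < 0 < res.acme_ci[1]
        assert abs(res.acme) < 0.1

    def test_planted_product_recovered_at_n2000(self, rng):
        df = _mediation_frame(rng, n=2000)
        res = mediate(df, "x", "m", "y", covariates=["age"], n_boot=500, seed=3)
        boot_se = (res.acme_ci[1] - res.acme_ci[0]) / 3.92
        assert abs(res.acme - 0.20) < 3 * boot_se
        se_ade = (res.ade_ci[1] - res.ade_ci[0]) / 3.92
        assert abs(res.ade - 0.30) < 3 * se_ade
        se_tot = (res.total_ci[1] - res.total_ci[0]) / 3.92
        assert abs(res.total - 0.50) < 3 * se_tot

    def test_seed_determinism(self, rng):
        df = _mediation_frame(rng, n=100)
        a = mediate(df, "x", "m", "y", n_boot=100, seed=5)
        b = mediate(df, "x", "m", "y", n_boot=100, seed=5)
        assert a.acme_ci == b.acme_ci and a.total_ci == b.total_ci

    def test_too_few_cases_rejected(self, rng):
        df = _mediation_frame(rng, n=10)
        with pytest.raises(ValueError, match="20"):
            mediate(df, "x", "m", "y")


class TestMediationBattery:
    def test_emits_ten_paths_in_canonical_order(self, cohort):
        out = mediation_battery(cohort, n_boot=30, seed=0)
        assert len(out) == 10
        expected = [f"{x} -> {m} -> {y}" for x, m, y in MEDIATION_PATHS]
        assert list(out["path"]) == expected

    def test_missing_variable_named(self, cohort):
        with pytest.raises(ValueError, match="ccbDzz"):
            mediation_battery(cohort.drop(columns=["ccbDzz"]), n_boot=10)

    def test_null_alps_total_effects_cover_zero(self, rng):
        """If the outcome is pure noise, the ten total-effect CIs should
        all cover zero."""
        n = 500
        cols = {v: rng.normal(size=n) for path in MEDIATION_PATHS for v in path[:2]}
        cols["ALPS"] = rng.normal(size=n)
        cols["age"] = rng.normal(size=n)
        df = pd.DataFrame(cols)
        out = mediation_battery(df, n_boot=200, seed=7)
        covers = (out["total_lo"] < 0) & (out["total_hi"] > 0)
        assert covers.all()

    def test_planted_chain_recovered(self, rng):
        """assocDxx -> ccbDyy -> ALPS with known a*b: the battery row
        recovers the product within 3 bootstrap SEs."""
        n = 1000
        a, b = 0.5, 0.4
        cols = {}
        x = rng.normal(size=n)
        med = a * x + rng.normal(scale=0.8, size=n)
        alps = b * med + rng.normal(scale=0.8, size=n)
        for path in MEDIATION_PATHS:
            for v in path[:2]:
                cols.setdefault(v, rng.normal(size=n))
        cols["assocDxx"] = x
        cols["ccbDyy"] = med
        cols["ALPS"] = alps
        cols["age"] = rng.normal(size=n)
        out = mediation_battery(pd.DataFrame(cols), n_boot=300, seed=11)
        row = out.set_index("path").loc["assocDxx -> ccbDyy -> ALPS"]
        se = (row["ACME_hi"] - row["ACME_lo"]) / 3.92
        assert abs(row["ACME"] - a * b) < 3 * se


class TestOneSampleT:
    def test_worked_example(self):
        t, df, p = one_sample_t([1.1, 1.2, 1.3], 1.0)
        assert t == pytest.approx(3.464, abs=1e-3)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_symmetric_sample_gives_t_zero(self):
        t, _, p = one_sample_t([0.9, 1.1, 0.8, 1.2], 1.0)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            one_sample_t([1.0, 1.0, 1.0], 1.0)

    def test_type_one_error_rate_near_nominal(self, rng):
        """Testing at the true mean rejects at ~5% over 2000 null draws
        (99% binomial band)."""
        rejections = 0
        n_sim, n = 2000, 20
        for _ in range(n_sim):
            x = rng.normal(loc=1.0, size=n)
            _, _, p = one_sample_t(x, 1.0)
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) < 2.576 * se

    def test_agrees_with_scipy(self, rng):
        from scipy import stats as sps

        x = rng.normal(loc=1.05, scale=0.1, size=30)
        t, _, p = one_sample_t(x, 1.0)
        ref = sps.ttest_1samp(x, 1.0)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestFdAlps:
    def test_perfect_dependence(self):
        df = pd.DataFrame({"mean_fd": np.linspace(0.1, 0.3, 20)})
        df["ALPS"] = df["mean_fd"]
        out = fd_alps_check(df)
        assert out["r"] == pytest.approx(1.0)

    def test_independent_columns_give_small_r(self, rng):
        df = pd.DataFrame({"mean_fd": rng.normal(size=100),
                           "ALPS": rng.normal(size=100)})
        assert abs(fd_alps_check(df)["r"]) < 0.3

    def test_default_cohort_ci_covers_zero_for_most_seeds(self):
        """FD is planted independent of ALPS; the Fisher-z CI should
        cover zero for at least 8 of 10 seeds."""
        from alpskit.cohort import CohortConfig, generate_cohort

        covered = 0
        for seed in range(10):
            t = generate_cohort(CohortConfig(seed=seed))
            out = fd_alps_check(t)
            covered += out["ci_low"] < 0 < out["ci_high"]
        assert covered >= 8
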