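"""Adjusted linear models, back-transformations, twin mixed models, FDR and
the pathway screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietmicro.associations import (
    bh_fdr,
    fit_adjusted_linear,
    fit_twin_mixed,
    pathway_screen,
    percent_diff_per_sd,
    quintile_backtransform,
    rank_probit,
)
from dietmicro.ffq import ID_COL


def hand_bh(pvalues):
    """Step-up BH oracle, straight from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, pvalues[i] * m / rank_from_top)
        adj[i] = value
        prev = value
    return adj


class TestBhFdr:
    def test_hand_example_four_pvalues(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_definition_oracle(self, pvalues):
        np.testing.assert_allclose(bh_fdr(pvalues), hand_bh(pvalues), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestRankProbit:
    def test_three_distinct_values_match_blom_arithmetic(self):
        # Phi^-1((r - 0.375) / 3.25) for r = 1, 2, 3
        out = rank_probit([10.0, 20.0, 30.0])
        np.testing.assert_allclose(out, [-0.8694237732888861, 0.0, 0.8694237732888861], atol=1e-3)

    def test_monotone_in_input(self, rng):
        x = rng.normal(size=100)
        out = rank_probit(x)
        assert (np.argsort(out) == np.argsort(x)).all()

    def test_approaches_standard_normal(self, rng):
        out = rank_probit(rng.gamma(2, 1, size=5000))
        assert abs(out.mean()) < 1e-8
        assert out.std(ddof=1) == pytest.approx(1.0, abs=0.02)

    def test_constant_vector_all_zeros(self):
        np.testing.assert_allclose(rank_probit([3.0, 3.0, 3.0]), 0.0)

    def test_ties_get_average_ranks(self):
        out = rank_probit([1.0, 1.0, 5.0])
        assert out[0] == out[1] < out[2]


class TestPercentDiff:
    def test_zero_beta_is_zero_percent(self):
        assert percent_diff_per_sd(0.0, -0.1, 0.1)[0] == 0.0

    def test_printed_value(self):
        pct, _, _ = percent_diff_per_sd(-0.0325, -0.05, -0.01)
        assert pct == pytest.approx(-3.1978, abs=1e-3)

    def test_monotone_in_beta(self):
        assert abs(percent_diff_per_sd(-0.06, 0, 0)[0]) > abs(percent_diff_per_sd(-0.03, 0, 0)[0])


def simulated_cohort(n, rng, slope=0.0, confounder=False):
    exposure = rng.normal(size=n)
    age = rng.uniform(30, 80, n)
    data = pd.DataFrame({
        ID_COL: [f"P{i:05d}" for i in range(n)],
        "exposure": exposure,
        "age": age,
    })
    y = slope * exposure + 0.01 * (age - 55) + rng.normal(0, 0.5, n)
    if confounder:
        data["bmi"] = 25 + 2.0 * exposure + rng.normal(0, 1, n)
        y = y + 0.1 * data["bmi"]
    data["y"] = y
    return data


class TestAdjustedLinear:
    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(42)
        data = simulated_cohort(2000, rng, slope=0.10)
        res = fit_adjusted_linear(data, "y", "exposure", covariates=("age",))
        assert res.beta == pytest.approx(0.10, abs=0.03)
        assert res.ci_low < res.beta < res.ci_high
        assert res.n == 2000

    def test_outcome_equal_to_exposure_in_noise_free_limit(self):
        rng = np.random.default_rng(0)
        data = simulated_cohort(200, rng)
        data["y"] = data["exposure"]
        res = fit_adjusted_linear(data, "y", "exposure", covariates=("age",))
        assert res.beta == pytest.approx(1.0, abs=1e-8)
        assert res.ci_high - res.ci_low < 1e-6

    def test_adjustment_removes_confounding(self):
        rng = np.random.default_rng(7)
        data = simulated_cohort(3000, rng, slope=0.10, confounder=True)
        adjusted = fit_adjusted_linear(data, "y", "exposure", covariates=("age",), include_bmi=True)
        crude = fit_adjusted_linear(data, "y", "exposure", covariates=("age",))
        assert adjusted.beta == pytest.approx(0.10, abs=0.04)
        assert crude.beta > 0.2  # absorbs the BMI path

    def test_rank_deficient_design_is_an_error(self):
        rng = np.random.default_rng(1)
        data = simulated_cohort(100, rng)
        data["age2"] = data["age"]
        with pytest.raises(ValueError, match="aliased"):
            fit_adjusted_linear(data, "y", "exposure", covariates=("age", "age2"))

    def test_standardized_exposure_scales_beta(self):
        rng = np.random.default_rng(3)
        data = simulated_cohort(500, rng, slope=0.2)
        data["exposure"] *= 4.0  # SD now 4, slope per unit 0.05
        res = fit_adjusted_linear(data, "y", "exposure", covariates=("age",),
                                  standardize_exposure=True)
        assert res.beta == pytest.approx(0.2, abs=0.07)


class TestQuintileBacktransform:
    @staticmethod
    def quintile_data(n, rng, q5_ratio=1.0):
        q = np.repeat([1, 2, 3, 4, 5], n // 5)
        age = rng.uniform(40, 70, len(q))
        log_y = np.log(2.0) + 0.002 * (age - 55) + rng.normal(0, 0.05, len(q))
        log_y = log_y + np.where(q == 5, np.log(q5_ratio), 0.0)
        return pd.DataFrame({ID_COL: [f"P{i}" for i in range(len(q))],
                             "q": q, "age": age, "log_y": log_y})

    def test_reference_quintile_is_exactly_one(self):
        rng = np.random.default_rng(5)
        out = quintile_backtransform(self.quintile_data(500, rng), "log_y", "q", covariates=("age",))
        assert out.loc[out["quintile"] == 1, "relative"].iloc[0] == 1.0

    def test_null_simulation_relative_values_near_one(self):
        rng = np.random.default_rng(6)
        out = quintile_backtransform(self.quintile_data(1500, rng), "log_y", "q", covariates=("age",))
        assert np.allclose(out["relative"], 1.0, atol=0.02)

    def test_absolute_values_on_outcome_scale(self):
        rng = np.random.default_rng(8)
        out = quintile_backtransform(self.quintile_data(1500, rng), "log_y", "q", covariates=("age",))
        assert np.allclose(out["absolute"], 2.0, rtol=0.05)


def twin_data(n_pairs, rng, pair_sd=1.0, resid_sd=1.0, slope=0.0):
    pair = np.repeat([f"T{i:04d}" for i in range(n_pairs)], 2)
    u = np.repeat(rng.normal(0, pair_sd, n_pairs), 2)
    exposure = rng.normal(size=2 * n_pairs)
    age = np.repeat(rng.uniform(30, 80, n_pairs), 2)
    y = slope * exposure + u + rng.normal(0, resid_sd, 2 * n_pairs)
    return pd.DataFrame({ID_COL: [f"P{i:05d}" for i in range(2 * n_pairs)],
                         "pair_id": pair, "zygosity": np.repeat(
                             np.where(rng.random(n_pairs) < 0.5, "MZ", "DZ"), 2),
                         "exposure": exposure, "age": age, "y": y})


class TestTwinMixed:
    def test_matches_ols_when_pair_variance_is_zero(self):
        rng = np.random.default_rng(11)
        data = twin_data(500, rng, pair_sd=0.0, slope=0.3)
        mixed = fit_twin_mixed(data, "y", "exposure", covariates=("age",))
        ols = fit_adjusted_linear(data, "y", "exposure", covariates=("age", "zygosity"))
        assert abs(mixed.beta - ols.beta) < 0.01

    def test_recovers_pair_variance_component(self):
        rng = np.random.default_rng(12)
        data = twin_data(500, rng, pair_sd=1.0, resid_sd=1.0)
        res = fit_twin_mixed(data, "y", "exposure", covariates=("age",))
        assert res.pair_variance == pytest.approx(1.0, abs=0.25)

    def test_shuffled_pair_labels_destroy_the_component(self):
        rng = np.random.default_rng(13)
        data = twin_data(500, rng, pair_sd=1.0, resid_sd=1.0)
        data["pair_id"] = rng.permutation(data["pair_id"].to_numpy())
        res = fit_twin_mixed(data, "y", "exposure", covariates=("age",))
        assert res.pair_variance < 0.15


class TestPathwayScreen:
    @staticmethod
    def build(n, rng, n_pathways=40, n_zero=5, planted=None):
        data = pd.DataFrame({ID_COL: [f"P{i:04d}" for i in range(n)],
                             "score": rng.normal(size=n),
                             "age": rng.uniform(30, 80, n)})
        data["q"] = pd.qcut(data["score"], 5, labels=[1, 2, 3, 4, 5]).astype(int)
        cols = {ID_COL: data[ID_COL]}
        planted = planted or {}
        for j in range(n_pathways):
            name = f"pw_{j + 1:03d}"
            beta = planted.get(name, 0.0)
            vals = np.exp(1.0 + beta * data["score"].to_numpy() + rng.normal(0, 0.5, n))
            if j < n_zero:
                vals[rng.random(n) < 0.95] = 0.0
            else:
                vals[rng.random(n) < 0.1] = 0.0
            cols[name] = vals
        return pd.DataFrame(cols), data

    def test_zero_rule_excludes_exactly_the_sparse_pathways(self):
        rng = np.random.default_rng(21)
        pw, data = self.build(400, rng, n_pathways=40, n_zero=5)
        res, _ = pathway_screen(pw, data, "score", covariates=("age",))
        assert res["excluded"].sum() == 5
        assert set(res.loc[res["excluded"], "pathway"]) == {f"pw_{j:03d}" for j in range(1, 6)}
        assert (~res["excluded"]).sum() == 35
        assert res.loc[res["excluded"], "beta"].isna().all()

    def test_planted_pathways_recovered_with_direction(self):
        rng = np.random.default_rng(22)
        planted = {f"pw_{j:03d}": 0.5 for j in range(10, 15)}
        planted.update({f"pw_{j:03d}": -0.5 for j in range(15, 20)})
        pw, data = self.build(500, rng, planted=planted)
        res, heat = pathway_screen(pw, data, "score", covariates=("age",), quintile_col="q")
        sig = res[res["fdr_p"] < 0.1]
        pos = set(sig.loc[sig["beta"] > 0, "pathway"])
        neg = set(sig.loc[sig["beta"] < 0, "pathway"])
        assert {f"pw_{j:03d}" for j in range(10, 15)} <= pos
        assert {f"pw_{j:03d}" for j in range(15, 20)} <= neg
        # heatmap: per pathway, z-scores across quintiles have mean 0 and SD 1
        assert not heat.empty
        np.testing.assert_allclose(heat.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(heat.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_monotone_planted_effect_shows_in_quintile_means(self):
        rng = np.random.default_rng(23)
        pw, data = self.build(500, rng, planted={"pw_030": 0.8})
        _, heat = pathway_screen(pw, data, "score", covariates=("age",), quintile_col="q")
        trend = heat["pw_030"].to_numpy()
        assert trend[-1] > trend[0]
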