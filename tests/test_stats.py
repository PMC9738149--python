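import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from boldvar.errors import DegenerateDesignError
from boldvar.stats import (
    build_design,
    fdr_adjust,
    ga_adjust,
    group_comparisons,
    ks_two_sample,
    moment_compare,
    ols_fit,
    run_battery,
    welch_t,
    wild_bootstrap_p,
)
from boldvar.synthdata import CohortSpec, generate_cohort


@pytest.fixture
def cohort():
    return generate_cohort(CohortSpec(n_subjects=100, noise_sd=0.1, hetero_scale=0.5, seed=42))


class TestBuildDesign:
    def test_main_effect_shape(self, cohort):
        d = build_design(cohort.head(10), "any_mrf")
        assert d.values.shape == (10, 3)
        assert d.columns == ["intercept", "ga_weeks", "any_mrf"]
        assert d.target_column == "any_mrf"

    def test_interaction_shape_and_product_column(self, cohort):
        d = build_design(cohort.head(20), "any_mrf", include_interaction=True)
        assert d.values.shape == (20, 5)
        np.testing.assert_array_equal(d.values[:, 4], d.values[:, 2] * d.values[:, 3])
        assert d.target_column == "any_mrf:chd"

    def test_all_chd_zero_interaction_degenerate(self, cohort):
        df = cohort.copy()
        df["chd"] = 0
        with pytest.raises(DegenerateDesignError):
            build_design(df, "any_mrf", include_interaction=True)

    def test_constant_predictor_degenerate(self, cohort):
        df = cohort.copy()
        df["obesity"] = 1
        with pytest.raises(DegenerateDesignError, match="constant"):
            build_design(df, "obesity")


class TestOlsFit:
    def test_exact_linear_fit(self, cohort):
        X = build_design(cohort, "any_mrf").values
        y = 2.0 + 0.3 * X[:, 1]
        beta, resid, _ = ols_fit(X, y)
        assert beta[1] == pytest.approx(0.3, abs=1e-10)
        assert np.abs(resid).max() < 1e-9

    def test_matches_normal_equations(self, rng):
        X = np.column_stack([np.ones(50), rng.random((50, 3))])
        y = rng.random(50)
        beta, resid, fitted = ols_fit(X, y)
        brute = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, brute, atol=1e-8)
        # residual orthogonality to every column
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_null_model_coefficient_small(self, rng):
        X = np.column_stack([np.ones(200), rng.integers(0, 2, 200).astype(float)])
        y = 1.0 + 0.1 * rng.standard_normal(200)
        beta, resid, _ = ols_fit(X, y)
        se = np.sqrt(
            (resid @ resid / (200 - 2)) * np.linalg.inv(X.T @ X)[1, 1]
        )
        assert abs(beta[1]) < 3 * se

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(DegenerateDesignError):
            ols_fit(X, np.arange(10.0))


class TestWildBootstrap:
    def test_strong_negative_effect_detected(self, cohort):
        design = build_design(cohort, "any_mrf")
        y = (
            5.0
            - 1.0 * cohort["any_mrf"].to_numpy()
            + 0.2 * np.random.default_rng(0).standard_normal(len(cohort))
        )
        res = wild_bootstrap_p(design, y, n_boot=1000, seed=1, direction="less")
        assert res.coefficient < -0.8
        assert res.p_one_sided < 0.01

    def test_null_p_near_half_under_symmetry(self, cohort):
        design = build_design(cohort, "any_mrf")
        rng = np.random.default_rng(5)
        ps = [
            wild_bootstrap_p(
                design,
                1.0 + 0.1 * rng.standard_normal(len(cohort)),
                n_boot=500,
                seed=s,
            ).p_one_sided
            for s in range(20)
        ]
        assert 0.2 < np.mean(ps) < 0.8

    def test_deterministic_under_seed(self, cohort):
        design = build_design(cohort, "diabetes")
        y = cohort["tv_placenta"].to_numpy()
        a = wild_bootstrap_p(design, y, n_boot=500, seed=3)
        b = wild_bootstrap_p(design, y, n_boot=500, seed=3)
        assert a.p_one_sided == b.p_one_sided

    def test_scale_invariance_exact(self, cohort):
        design = build_design(cohort, "any_mrf")
        y = cohort["tv_placenta"].to_numpy()
        p1 = wild_bootstrap_p(design, y, n_boot=500, seed=7).p_one_sided
        p2 = wild_bootstrap_p(design, 100.0 * y, n_boot=500, seed=7).p_one_sided
        assert p1 == p2

    def test_rescaling_ga_column_invariant(self, cohort):
        design = build_design(cohort, "any_mrf")
        y = cohort["tv_placenta"].to_numpy()
        scaled = build_design(
            cohort.assign(ga_weeks=cohort.ga_weeks * 7.0), "any_mrf"
        )
        p1 = wild_bootstrap_p(design, y, n_boot=500, seed=7).p_one_sided
        p2 = wild_bootstrap_p(scaled, y, n_boot=500, seed=7).p_one_sided
        assert p1 == p2

    def test_small_n_boot_rejected(self, cohort):
        design = build_design(cohort, "any_mrf")
        with pytest.raises(ValueError, match="n_boot"):
            wild_bootstrap_p(design, cohort["tv_placenta"].to_numpy(), n_boot=50)


class TestFdrAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust(np.ones(5)), 1.0)

    def test_single_p_identity(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.123])), [0.123])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_never_decreases_and_subset_property(self, ps):
        p = np.array(ps)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # significant-after is a subset of significant-before
        assert set(np.flatnonzero(adj < 0.05)) <= set(np.flatnonzero(p < 0.05))


class TestGaAdjust:
    def test_perfect_linear_fit_residuals_zero(self, rng):
        ga = rng.uniform(27, 40, 30)
        values = 1.0 + 0.2 * ga
        np.testing.assert_allclose(ga_adjust(values, ga), 0.0, atol=1e-10)

    def test_residuals_uncorrelated_with_ga(self, rng):
        ga = rng.uniform(27, 40, 100)
        values = rng.standard_normal(100)
        resid = ga_adjust(values, ga)
        assert abs(np.corrcoef(resid, ga)[0, 1]) < 1e-10
        assert abs(resid.mean()) < 1e-10

    def test_constant_ga_centers_values(self, rng, caplog):
        import logging

        values = rng.standard_normal(20)
        with caplog.at_level(logging.WARNING):
            resid = ga_adjust(values, np.full(20, 30.0))
        np.testing.assert_allclose(resid, values - values.mean())


class TestKsTwoSample:
    def test_identical_samples(self, rng):
        a = rng.standard_normal(30)
        D, _ = ks_two_sample(a, a)
        assert D == pytest.approx(0.0, abs=1e-12)

    def test_fully_separated(self, rng):
        D, p = ks_two_sample(np.arange(10.0), np.arange(100.0, 110.0))
        assert D == pytest.approx(1.0)
        assert p < 0.001

    def test_undersized_group_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 5"):
            ks_two_sample(np.arange(3.0), rng.standard_normal(20))


class TestMomentCompare:
    def test_identical_groups(self, rng):
        a = rng.standard_normal(50)
        out = moment_compare(a, a.copy(), n_permutations=200, seed=0)
        F, p_var = out["variance"]
        assert F == pytest.approx(1.0)
        assert p_var == pytest.approx(1.0, abs=1e-9)
        assert out["skewness"][1] > 0.5
        assert out["kurtosis"][1] > 0.5

    def test_variance_ratio_detected(self, rng):
        a = rng.standard_normal(200)
        b = 2.0 * rng.standard_normal(200)
        out = moment_compare(a, b, n_permutations=200, seed=1)
        assert out["variance"][1] < 0.001

    def test_skewed_sample_detected_majority_of_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(500)
            b = rng.gamma(2.0, 1.0, 500)
            b = (b - b.mean()) / b.std() * a.std()  # equal scale, skewed shape
            out = moment_compare(a, b, n_permutations=500, seed=seed)
            hits += out["skewness"][1] < 0.05
        assert hits >= 8

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            moment_compare(np.ones(20), rng.standard_normal(20))


class TestWelchT:
    def test_identical_summaries(self):
        t, p = welch_t((1.0, 2.0, 30), (1.0, 2.0, 30))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_formula(self):
        t, p = welch_t((0.0, 1.0, 50), (1.0, 1.0, 50))
        assert t == pytest.approx(-5.0, abs=1e-12)
        assert p < 1e-5

    def test_raw_equals_summary(self, rng):
        a = rng.standard_normal(40) + 0.3
        b = rng.standard_normal(35)
        t_raw, p_raw = welch_t(a, b)
        t_sum, p_sum = welch_t(
            (a.mean(), a.std(ddof=1), a.size), (b.mean(), b.std(ddof=1), b.size)
        )
        assert t_raw == pytest.approx(t_sum, abs=1e-10)
        assert p_raw == pytest.approx(p_sum, abs=1e-10)

    def test_matches_scipy(self, rng):
        a = rng.standard_normal(40)
        b = 2.0 * rng.standard_normal(35) + 0.5
        t_ours, p_ours = welch_t(a, b)
        res = sps.ttest_ind(a, b, equal_var=False)
        assert t_ours == pytest.approx(res.statistic, abs=1e-10)
        assert p_ours == pytest.approx(res.pvalue, abs=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_t((0.0, 1.0, 1), (1.0, 1.0, 50))


class TestRunBattery:
    def test_row_layout(self, cohort):
        out = run_battery(cohort, n_boot=200, seed=0)
        assert len(out) == 4 * 2 * 2 * 2  # metrics x tissues x predictors... flattened
        assert set(out["tissue"]) == {"placenta", "brain"}
        assert set(out["metric"]) == {"tv", "sv"}
        assert set(out["effect_type"]) == {"main", "interaction"}
        assert len(out[out.status == "ok"]) > 0

    def test_degenerate_rows_report_status_not_number(self):
        df = generate_cohort(
            CohortSpec(
                n_subjects=40,
                prev_obesity=0.0,
                prev_hypertension=0.0,
                prev_diabetes=0.0,
                seed=3,
            )
        )
        out = run_battery(df, metric_columns=["tv_placenta"], n_boot=200, seed=0)
        degenerate = out[out.predictor == "any_mrf"]
        assert (degenerate.status == "degenerate_design").all()
        assert degenerate.coefficient.isna().all()

    def test_fdr_within_family(self, cohort):
        out = run_battery(cohort, metric_columns=["tv_placenta"], n_boot=200, seed=0)
        block = out[(out.effect_type == "main") & (out.status == "ok")]
        expected = fdr_adjust(block["p_one_sided"].to_numpy())
        np.testing.assert_allclose(block["p_fdr"].to_numpy(), expected)


class TestGroupComparisons:
    def test_structure_and_keys(self, cohort):
        out = group_comparisons(cohort, metric_columns=["tv_placenta"], seed=0, n_permutations=100)
        entry = out["tv_placenta"]
        assert {"ks", "moments", "welch_t"} <= set(entry)
        assert 0 <= entry["ks"]["p"] <= 1
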