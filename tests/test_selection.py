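"""Variable-selection chain, per-region regression, and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
from oracles import greedy_collinearity_oracle, pearson_oracle

from maizecast.features import FeatureTable
from maizecast.selection import (
    collinearity_filter,
    diagnostics,
    drop_zero_variance,
    fit_region_model,
    lasso_select,
    select_features,
)

YEARS = list(range(2010, 2020))


def _table(cols) -> FeatureTable:
    df = pd.DataFrame(cols, index=pd.Index(YEARS[: len(next(iter(cols.values())))], name="year"))
    return FeatureTable("X", df.astype(float), {c: "v" for c in df.columns})


def _random_table(rng, n_cols=8, n_years=10, collinear_pairs=2):
    X = rng.normal(0, 1, (n_years, n_cols))
    for k in range(collinear_pairs):  # manufacture strongly collinear pairs
        X[:, n_cols - 1 - k] = X[:, k] + rng.normal(0, 0.2, n_years)
    cols = {f"f{i:02d}": X[:, i] for i in range(n_cols)}
    return _table(cols)


class TestZeroVariance:
    def test_constant_column_removed_others_kept_in_order(self):
        ft = _table({"a": np.ones(10), "b": np.arange(10), "c": np.arange(10) ** 2})
        out = drop_zero_variance(ft, YEARS)
        assert out.columns == ["b", "c"]

    def test_all_columns_constant_is_an_error(self):
        ft = _table({"a": np.ones(10), "b": np.full(10, 5.0)})
        with pytest.raises(ValueError, match="no informative predictors"):
            drop_zero_variance(ft, YEARS)

    def test_matches_brute_force_sd_check(self, rng):
        X = rng.normal(0, 1, (10, 6))
        X[:, 2] = 3.0
        X[:, 5] = -1.0
        ft = _table({f"f{i}": X[:, i] for i in range(6)})
        out = drop_zero_variance(ft, YEARS)
        expected = [f"f{i}" for i in range(6) if np.std(X[:, i]) > 0]
        assert out.columns == expected


class TestCollinearityFilter:
    def test_duplicated_column_keeps_the_better_yield_correlate(self, rng):
        x = rng.normal(0, 1, 10)
        y = pd.Series(x + rng.normal(0, 0.1, 10), index=YEARS)
        ft = _table({"dup_a": x, "dup_b": x + rng.normal(0, 0.01, 10)})
        out = collinearity_filter(ft, y, YEARS)
        assert len(out.columns) == 1
        kept = out.columns[0]
        other = "dup_b" if kept == "dup_a" else "dup_a"
        assert abs(pearson_oracle(ft.df[kept], y)) >= abs(pearson_oracle(ft.df[other], y))

    def test_orthogonal_columns_pass_unchanged(self):
        ft = _table({"a": np.eye(10)[0], "b": np.eye(10)[1], "c": np.eye(10)[2]})
        y = pd.Series(np.arange(10, dtype=float), index=YEARS)
        assert collinearity_filter(ft, y, YEARS).columns == ["a", "b", "c"]

    def test_matches_greedy_oracle_and_bounds_pairwise_r(self, rng):
        for _ in range(25):
            ft = _random_table(rng)
            y = pd.Series(rng.normal(0, 1, 10), index=YEARS)
            out = collinearity_filter(ft, y, YEARS)
            assert out.columns == greedy_collinearity_oracle(ft.df, y.to_numpy())
            corr = out.df.corr().abs().to_numpy()
            np.fill_diagonal(corr, 0)
            assert corr.max() <= 0.7 + 1e-12


class TestLassoSelect:
    def test_planted_signal_is_selected(self, rng):
        X = rng.normal(0, 1, (10, 8))
        ft = _table({f"f{i}": X[:, i] for i in range(8)}).standardize(YEARS)
        y = pd.Series(2.0 * ft.df["f3"].to_numpy(), index=YEARS)
        assert "f3" in lasso_select(ft, y, YEARS, 5)

    def test_cardinality_cap_at_five(self, rng):
        X = rng.normal(0, 1, (10, 10))
        ft = _table({f"f{i}": X[:, i] for i in range(10)}).standardize(YEARS)
        beta = rng.uniform(0.5, 1.0, 10)
        y = pd.Series(ft.df.to_numpy() @ beta, index=YEARS)
        assert len(lasso_select(ft, y, YEARS, 5)) <= 5

    def test_zero_anomalies_select_nothing(self, rng):
        X = rng.normal(0, 1, (10, 6))
        ft = _table({f"f{i}": X[:, i] for i in range(6)}).standardize(YEARS)
        assert lasso_select(ft, pd.Series(np.zeros(10), index=YEARS), YEARS, 5) == []


class TestFitRegionModel:
    def test_exact_single_feature_fit(self, rng):
        x = rng.normal(0, 1, 10)
        ft = _table({"a": x})
        y = pd.Series(0.7 * x, index=YEARS)
        fit = fit_region_model(ft, y, YEARS, ["a"])
        assert fit.betas[0] == pytest.approx(0.7)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_empty_selection_predicts_the_mean(self, rng):
        ft = _table({"a": rng.normal(0, 1, 10)})
        y = pd.Series(rng.normal(0, 1, 10), index=YEARS)
        fit = fit_region_model(ft, y, YEARS, [])
        assert (fit.fitted == 0).all()
        assert fit.predict(ft.df).eq(0).all()

    def test_residuals_sum_to_zero_on_standardized_design(self, rng):
        # demeaned response + zero-mean standardized columns -> OLS without
        # intercept still yields mean-zero residuals
        X = rng.normal(0, 1, (10, 3))
        ft = _table({f"f{i}": X[:, i] for i in range(3)}).standardize(YEARS)
        y0 = rng.normal(0, 1, 10)
        y = pd.Series(y0 - y0.mean(), index=YEARS)
        fit = fit_region_model(ft, y, YEARS, ft.columns)
        assert abs(fit.residuals.mean()) < 1e-8

    def test_rank_deficient_design_is_an_error(self, rng):
        x = rng.normal(0, 1, 10)
        ft = _table({"a": x, "b": 2 * x})
        y = pd.Series(x, index=YEARS)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_region_model(ft, y, YEARS, ["a", "b"])

    def test_too_many_predictors_rejected(self, rng):
        X = rng.normal(0, 1, (4, 5))
        years = YEARS[:4]
        df = pd.DataFrame({f"f{i}": X[:, i] for i in range(5)}, index=years)
        ft = FeatureTable("X", df, {c: "v" for c in df.columns})
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_region_model(ft, pd.Series(np.zeros(4), index=years), years, ft.columns)


class TestSelectionChainRecovery:
    def test_planted_model_recovered_with_small_noise(self, rng):
        # noise_sd=0.01, T=10: the chain finds the planted feature and OLS
        # recovers its coefficient within +/-0.05
        for _ in range(5):
            X = rng.normal(0, 1, (10, 12))
            ft = _table({f"f{i:02d}": X[:, i] for i in range(12)}).standardize(YEARS)
            y = pd.Series(
                0.6 * ft.df["f04"].to_numpy() + rng.normal(0, 0.01, 10), index=YEARS
            )
            sel = select_features(ft, y, YEARS, 5)
            assert "f04" in sel
            fit = fit_region_model(ft, y, YEARS, sel)
            beta = dict(zip(fit.selected_features, fit.betas))["f04"]
            assert abs(beta - 0.6) <= 0.05


class TestDiagnostics:
    def test_orthogonal_design_has_unit_vifs(self):
        # mean-zero mutually orthogonal Fourier columns
        t = np.arange(10)
        X = np.column_stack(
            [np.cos(2 * np.pi * t / 10), np.sin(2 * np.pi * t / 10), np.cos(4 * np.pi * t / 10)]
        )
        ft = _table({f"f{i}": X[:, i] for i in range(3)})
        y = pd.Series(X @ np.array([1.0, -1.0, 0.5]) + 0.01 * X[:, 0], index=YEARS)
        fit = fit_region_model(ft, y, YEARS, ft.columns)
        rep = diagnostics(fit, ft)
        assert rep.applicable
        assert all(v == pytest.approx(1.0, abs=1e-6) for v in rep.vif_per_feature.values())
        assert 0 <= rep.breusch_godfrey_p <= 1
        assert 0 <= rep.breusch_pagan_p <= 1

    def test_empty_selection_yields_not_applicable_report(self, rng):
        ft = _table({"a": rng.normal(0, 1, 10)})
        fit = fit_region_model(ft, pd.Series(np.zeros(10), index=YEARS), YEARS, [])
        rep = diagnostics(fit, ft)
        assert not rep.applicable
        assert "not applicable" in rep.note

    def test_breusch_godfrey_type_one_error_near_nominal(self):
        # iid Gaussian residuals: the lag-1 BG test should reject at 5%
        # roughly 5% of the time (simulated at n=50 where the chi2
        # approximation is adequate)
        rng = np.random.default_rng(77)
        years = list(range(1970, 2020))
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            X = rng.normal(0, 1, (50, 2))
            df = pd.DataFrame({"a": X[:, 0], "b": X[:, 1]}, index=years)
            ft = FeatureTable("X", df, {"a": "v", "b": "v"})
            y = pd.Series(X @ np.array([0.5, -0.5]) + rng.normal(0, 1, 50), index=years)
            fit = fit_region_model(ft, y, years, ["a", "b"])
            rejections += diagnostics(fit, ft).breusch_godfrey_p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09
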