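"""Two-level leave-one-year-out validation, independent holdout forecast,
absolute-yield reconstruction, and skill scores.

Level 1 selects predictors once on all years, then refits coefficients
(and the trend and standardization, on training years only) in each fold.
Level 2 reruns the entire selection chain inside every fold with a cap of
4 predictors, so no information from the held-out year enters selection,
standardization, detrending, or fitting — the operational-forecast
setting. The holdout forecast trains on all but the final year and
extrapolates the trend one year ahead.

Skill is measured by the Nash-Sutcliffe efficiency, NSE = 1 - SSE/SS_tot
(1 = perfect, 0 = no better than the observation mean, unbounded below),
and RMSE — on the log-anomaly scale and, after retrending, in t/ha. A
constant model (leave-one-year-out mean yield) provides the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable
from .selection import (
    MAX_VARS_ESTIMATION,
    MAX_VARS_LEVEL2,
    fit_region_model,
    prune_rank_deficient,
    select_features,
)
from .yields import YieldSeries, detrend


def nse(obs, pred) -> float:
    """Nash-Sutcliffe efficiency: 1 - SSE / SS_tot about the observed mean."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(obs) < 2 or len(obs) != len(pred):
        raise ValueError("need at least 2 aligned observation/prediction pairs")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("NSE undefined: zero observed variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def rmse(obs, pred) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(obs) == 0 or len(obs) != len(pred):
        raise ValueError("need at least 1 aligned observation/prediction pair")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


@dataclass
class ValidationReport:
    """Out-of-sample predictions and scores for one region and level.

    ``table`` has one row per held-out year: observed/predicted log
    anomalies (each fold's anomaly is relative to that fold's training
    trend), observed/predicted absolute yields, and the trend-only
    prediction.
    """

    region: str
    level: str  # full | level1 | level2 | holdout
    table: pd.DataFrame
    nse_anom: float | None
    rmse_anom: float
    nse_abs: float | None
    rmse_abs: float
    baseline_rmse: float | None = None
    selected: tuple[str, ...] | None = None
    selected_per_fold: dict[int, tuple[str, ...]] = field(default_factory=dict)
    fold_trends: dict[int, object] = field(default_factory=dict)
    fold_betas: dict[int, np.ndarray] = field(default_factory=dict)
    fold_std_params: dict[int, dict] = field(default_factory=dict)

    def component_scores(self) -> dict[str, float]:
        """NSE of the trend-only, anomaly, and combined predictions."""
        t = self.table
        return {
            "nse_trend_abs": nse(t["obs_yield"], t["trend_yield"]),
            "nse_anom": nse(t["obs_anom"], t["pred_anom"]),
            "nse_combined_abs": nse(t["obs_yield"], t["pred_yield"]),
        }


def _score(table: pd.DataFrame) -> tuple[float | None, float, float | None, float]:
    try:
        n_a = nse(table["obs_anom"], table["pred_anom"])
    except ValueError:
        n_a = None
    try:
        n_y = nse(table["obs_yield"], table["pred_yield"])
    except ValueError:
        n_y = None
    return (
        n_a,
        rmse(table["obs_anom"], table["pred_anom"]),
        n_y,
        rmse(table["obs_yield"], table["pred_yield"]),
    )


def _fit_fold(
    features: FeatureTable,
    yields: YieldSeries,
    train_years: list[int],
    test_year: int,
    selected: list[str] | None,
    scope: str,
    max_vars: int,
):
    """Train on ``train_years`` only and predict ``test_year``.

    Trend, standardization and (when ``selected`` is None) the whole
    selection chain are computed from the training years, so nothing about
    the held-out year leaks into the fold.
    """
    train = yields.subset(train_years)
    anomalies, trend = detrend(train, train_years)
    ft = features.subset_scope(scope).standardize(train_years)
    if selected is None:
        sel = select_features(ft, anomalies, train_years, max_vars)
    else:  # pre-selected set; drop members degenerate within this fold
        sel = [c for c in selected if c in ft.std_params]
    sel = prune_rank_deficient(ft, train_years, sel)
    fit = fit_region_model(ft, anomalies, train_years, sel)

    x_test = ft.df.loc[[test_year]]
    pred_anom = float(fit.predict(x_test).iloc[0])
    trend_log = float(trend.predict([test_year])[0])
    obs_yield = float(yields.subset([test_year]).values[0])
    row = {
        "year": test_year,
        "obs_anom": float(np.log(obs_yield) - trend_log),
        "pred_anom": pred_anom,
        "obs_yield": obs_yield,
        "pred_yield": float(np.exp(pred_anom + trend_log)),
        "trend_yield": float(np.exp(trend_log)),
    }
    return row, sel, trend, fit, ft


def loocv_level1(
    features: FeatureTable,
    yields: YieldSeries,
    scope: str = "estimation",
    max_vars: int = MAX_VARS_ESTIMATION,
) -> ValidationReport:
    """Level-1 LOOCV: pre-processing (detrend, standardization) and variable
    selection happen once on the complete series; only the regression
    coefficients are refit on the remaining years in each fold. Level 2 is
    the fully out-of-sample counterpart."""
    years = [int(y) for y in yields.years]
    if len(years) < 5:
        raise ValueError("need at least 5 years for leave-one-year-out validation")
    anomalies, trend = detrend(yields, years)
    ft = features.subset_scope(scope).standardize(years)
    selected = select_features(ft, anomalies, years, max_vars)

    rows = []
    report = ValidationReport("", "level1", pd.DataFrame(), None, 0.0, None, 0.0)
    for test_year in years:
        train_years = [y for y in years if y != test_year]
        try:
            sel = prune_rank_deficient(ft, train_years, selected)
            fit = fit_region_model(ft, anomalies, train_years, sel)
        except ValueError as err:
            raise ValueError(f"level-1 fold for year {test_year} failed: {err}") from err
        pred_anom = float(fit.predict(ft.df.loc[[test_year]]).iloc[0])
        trend_log = float(trend.predict([test_year])[0])
        obs_yield = float(yields.subset([test_year]).values[0])
        rows.append(
            {
                "year": test_year,
                "obs_anom": float(anomalies.loc[test_year]),
                "pred_anom": pred_anom,
                "obs_yield": obs_yield,
                "pred_yield": float(np.exp(pred_anom + trend_log)),
                "trend_yield": float(np.exp(trend_log)),
            }
        )
        report.fold_trends[test_year] = trend
        report.fold_betas[test_year] = fit.betas
        report.fold_std_params[test_year] = ft.std_params
    table = pd.DataFrame(rows).set_index("year")
    report.region = yields.region
    report.table = table
    report.nse_anom, report.rmse_anom, report.nse_abs, report.rmse_abs = _score(table)
    report.selected = tuple(selected)
    report.baseline_rmse = constant_baseline(yields)[1]
    return report


def loocv_level2(
    features: FeatureTable,
    yields: YieldSeries,
    scope: str = "estimation",
    max_vars: int = MAX_VARS_LEVEL2,
) -> ValidationReport:
    """Level-2 LOOCV: the entire selection chain reruns inside every fold
    (cap 4), simulating the operational forecast."""
    years = [int(y) for y in yields.years]
    if len(years) < 5:
        raise ValueError("need at least 5 years for leave-one-year-out validation")
    rows = []
    report = ValidationReport("", "level2", pd.DataFrame(), None, 0.0, None, 0.0)
    for test_year in years:
        train_years = [y for y in years if y != test_year]
        try:
            row, sel, trend, fit, ft = _fit_fold(
                features, yields, train_years, test_year, None, scope, max_vars
            )
        except ValueError as err:
            raise ValueError(f"level-2 fold for year {test_year} failed: {err}") from err
        rows.append(row)
        report.selected_per_fold[test_year] = tuple(sel)
        report.fold_trends[test_year] = trend
        report.fold_betas[test_year] = fit.betas
        report.fold_std_params[test_year] = ft.std_params
    table = pd.DataFrame(rows).set_index("year")
    report.region = yields.region
    report.table = table
    report.nse_anom, report.rmse_anom, report.nse_abs, report.rmse_abs = _score(table)
    report.baseline_rmse = constant_baseline(yields)[1]
    return report


def holdout_forecast(
    features: FeatureTable,
    yields: YieldSeries,
    train_years,
    test_year: int,
    scope: str = "forecast",
    max_vars: int = MAX_VARS_ESTIMATION,
) -> ValidationReport:
    """Completely independent forecast of ``test_year``: the full chain runs
    on the training years only and the trend is extrapolated one year ahead."""
    train_years = [int(y) for y in train_years]
    test_year = int(test_year)
    if test_year in train_years:
        raise ValueError("test year must not be part of the training years")
    if test_year != max(train_years) + 1:
        raise ValueError("test year must directly follow the training years")
    row, sel, trend, fit, ft = _fit_fold(
        features, yields, train_years, test_year, None, scope, max_vars
    )
    table = pd.DataFrame([row]).set_index("year")
    report = ValidationReport(
        yields.region,
        "holdout",
        table,
        None,
        rmse(table["obs_anom"], table["pred_anom"]),
        None,
        rmse(table["obs_yield"], table["pred_yield"]),
        selected=tuple(sel),
    )
    report.fold_trends[test_year] = trend
    report.fold_betas[test_year] = fit.betas
    report.fold_std_params[test_year] = ft.std_params
    return report


def constant_baseline(yields: YieldSeries, years=None) -> tuple[pd.Series, float]:
    """Constant model: predict each year's yield by the mean of all OTHER
    years' observed yields; returns per-year predictions and their RMSE."""
    ys = yields if years is None else yields.subset(years)
    n = len(ys.years)
    if n < 2:
        raise ValueError("constant baseline needs at least 2 years")
    total = ys.values.sum()
    preds = (total - ys.values) / (n - 1)
    return pd.Series(preds, index=ys.years), rmse(ys.values, preds)


def pooled_group_nse(reports: dict[str, ValidationReport], groups: dict[str, str]) -> dict[str, float]:
    """NSE pooled across regions per group (e.g. unimodal/bimodal), with the
    group mean of the observations as the reference — used for single-year
    holdout forecasts where per-region NSE is undefined."""
    out: dict[str, float] = {}
    for group in sorted(set(groups.values())):
        obs, pred = [], []
        for region, rep in reports.items():
            if groups[region] == group:
                obs.extend(rep.table["obs_yield"].tolist())
                pred.extend(rep.table["pred_yield"].tolist())
        if len(obs) >= 2:
            out[group] = nse(obs, pred)
    return out


def reports_to_frame(reports: dict[str, ValidationReport]) -> pd.DataFrame:
    """Long per-year table across regions for CSV export."""
    rows = []
    for region, rep in reports.items():
        t = rep.table.reset_index()
        t.insert(0, "region", region)
        t.insert(1, "level", rep.level)
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def summary_frame(reports: dict[str, ValidationReport]) -> pd.DataFrame:
    rows = []
    for region, rep in reports.items():
        n_feats = (
            len(rep.selected)
            if rep.selected is not None
            else int(np.median([len(s) for s in rep.selected_per_fold.values()]))
            if rep.selected_per_fold
            else 0
        )
        rows.append(
            {
                "region": region,
                "level": rep.level,
                "nse_anom": rep.nse_anom,
                "rmse_anom": rep.rmse_anom,
                "nse_abs": rep.nse_abs,
                "rmse_abs": rep.rmse_abs,
                "baseline_rmse": rep.baseline_rmse,
                "n_features": n_feats,
            }
        )
    return pd.DataFrame(rows)
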