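"""Four-step variable selection and the per-region regression with diagnostics.

Selection chain, applied to the standardized feature table and the
detrended log-yield anomalies of one region:

1. drop predictors with zero variance over the fit years;
2. resolve strong collinearity: among pairs with |Pearson r| > 0.7
   (processed in descending |r|), keep the member more correlated with the
   yield anomalies;
3. LASSO with the penalty chosen by leave-one-year-out cross-validated MSE
   on a fixed log-spaced grid (ties toward the larger penalty, i.e. the
   sparser fit);
4. cap the selection at ``max_vars`` predictors (5 for estimation and
   level-1 validation, 4 inside level-2 folds), keeping those most
   correlated with the anomalies.

The regional model is OLS without intercept — the response is already
demeaned and detrended — giving standardized coefficients (log-yield
change per standard deviation of each predictor). Residual diagnostics:
Breusch-Godfrey (lag 1) for autocorrelation, studentized Breusch-Pagan for
heteroscedasticity, and variance inflation factors for multicollinearity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from statsmodels.stats.diagnostic import acorr_breusch_godfrey, het_breuschpagan

from .features import FeatureTable

R_COLLINEAR = 0.7
MAX_VARS_ESTIMATION = 5
MAX_VARS_LEVEL2 = 4
LAMBDA_GRID_SIZE = 100
LAMBDA_MIN_RATIO = 1e-4


def _safe_abs_r(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(abs(stats.pearsonr(x, y)[0]))


def drop_zero_variance(features: FeatureTable, fit_years) -> FeatureTable:
    """Remove predictors without year-to-year variation over the fit years."""
    fit = features.df.loc[list(fit_years)]
    dead = [c for c in fit.columns if fit[c].std(ddof=1) == 0]
    out = features.drop(dead)
    if not out.columns:
        raise ValueError("no informative predictors: all columns have zero variance")
    return out


def collinearity_filter(
    features: FeatureTable,
    anomalies: pd.Series,
    fit_years,
    r_threshold: float = R_COLLINEAR,
) -> FeatureTable:
    """Resolve pairs with |Pearson r| > ``r_threshold``, keeping per pair the
    predictor more correlated with the yield anomalies.

    Pairs are processed in descending |r| with a lexicographic tie rule, so
    the result is deterministic; afterwards all surviving pairs satisfy
    |r| <= r_threshold.
    """
    fit_years = list(fit_years)
    X = features.df.loc[fit_years]
    y = anomalies.loc[fit_years].to_numpy(dtype=float)
    cols = list(X.columns)
    if len(cols) < 2:
        return features
    corr = X.corr().abs().to_numpy()
    np.nan_to_num(corr, copy=False)
    r_with_y = {c: _safe_abs_r(X[c].to_numpy(dtype=float), y) for c in cols}

    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if corr[i, j] > r_threshold:
                pairs.append((corr[i, j], cols[i], cols[j]))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    alive = set(cols)
    for _, a, b in pairs:
        if a in alive and b in alive:
            if r_with_y[a] > r_with_y[b]:
                alive.discard(b)
            elif r_with_y[b] > r_with_y[a]:
                alive.discard(a)
            else:  # tie: drop the lexicographically later name
                alive.discard(max(a, b))
    return features.drop([c for c in cols if c not in alive])


def lambda_grid(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fixed log-spaced penalty grid from lambda_max (all coefficients zero)
    down to lambda_max * 1e-4, in the sklearn (1/2n) objective scaling."""
    lam_max = float(np.max(np.abs(X.T @ y)) / len(y))
    if lam_max == 0:
        return np.array([])
    return np.geomspace(lam_max, lam_max * LAMBDA_MIN_RATIO, LAMBDA_GRID_SIZE)


def lasso_select(
    features: FeatureTable,
    anomalies: pd.Series,
    fit_years,
    max_vars: int = MAX_VARS_ESTIMATION,
) -> list[str]:
    """LASSO selection (no intercept) with the penalty chosen by
    leave-one-year-out CV MSE; at most ``max_vars`` survivors, ranked by
    |Pearson r| with the anomalies when the cap binds."""
    fit_years = list(fit_years)
    if len(fit_years) < 4:
        raise ValueError("need at least 4 fit years for LASSO selection")
    cols = features.columns
    X = features.df.loc[fit_years, cols].to_numpy(dtype=float)
    y = anomalies.loc[fit_years].to_numpy(dtype=float)
    grid = lambda_grid(X, y)
    if grid.size == 0:
        return []

    cv_sse = np.zeros(len(grid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(len(fit_years)):
            tr = np.arange(len(fit_years)) != k
            _, coefs, _ = lasso_path(X[tr], y[tr], alphas=grid, max_iter=10_000)
            preds = X[k] @ coefs  # (n_alphas,)
            cv_sse += (y[k] - preds) ** 2
    best = int(np.argmin(cv_sse))  # grid descends, argmin ties -> larger lambda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = Lasso(alpha=grid[best], fit_intercept=False, max_iter=100_000).fit(X, y)
    selected = [c for c, b in zip(cols, fit.coef_) if b != 0.0]
    if len(selected) > max_vars:
        ranked = sorted(
            selected,
            key=lambda c: (-_safe_abs_r(features.df.loc[fit_years, c].to_numpy(dtype=float), y), c),
        )
        selected_set = set(ranked[:max_vars])
        selected = [c for c in selected if c in selected_set]
    return selected


def select_features(
    features: FeatureTable,
    anomalies: pd.Series,
    fit_years,
    max_vars: int = MAX_VARS_ESTIMATION,
    r_threshold: float = R_COLLINEAR,
) -> list[str]:
    """The full selection chain: zero-variance filter, collinearity filter,
    LASSO with LOO-CV penalty, cardinality cap."""
    ft = drop_zero_variance(features, fit_years)
    ft = collinearity_filter(ft, anomalies, fit_years, r_threshold)
    return lasso_select(ft, anomalies, fit_years, max_vars)


def prune_rank_deficient(features: FeatureTable, fit_years, selected: list[str]) -> list[str]:
    """Drop later columns that are exactly linearly dependent on earlier ones
    over ``fit_years`` (can happen with discrete count features on few years)."""
    X = features.df.loc[list(fit_years)]
    keep: list[str] = []
    for c in selected:
        cand = X[keep + [c]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(c)
    return keep


@dataclass
class FitResult:
    """Per-region OLS fit of standardized predictors on yield anomalies."""

    region: str
    selected_features: tuple[str, ...]
    betas: np.ndarray
    residuals: pd.Series
    fitted: pd.Series
    fit_years: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.selected_features)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        if self.k == 0:
            return pd.Series(np.zeros(len(X)), index=X.index)
        return pd.Series(
            X[list(self.selected_features)].to_numpy(dtype=float) @ self.betas, index=X.index
        )

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "selected_features": list(self.selected_features),
            "betas": list(self.betas),
            "fit_years": list(self.fit_years),
        }


def fit_region_model(
    features: FeatureTable,
    anomalies: pd.Series,
    fit_years,
    selected: list[str],
) -> FitResult:
    """OLS without intercept of anomalies on the selected standardized
    predictors; with an empty selection the model predicts 0 (the mean)."""
    fit_years = tuple(int(y) for y in fit_years)
    if len(selected) >= len(fit_years):
        raise ValueError("more predictors than residual degrees of freedom")
    y = anomalies.loc[list(fit_years)]
    if not selected:
        zeros = pd.Series(np.zeros(len(fit_years)), index=list(fit_years))
        return FitResult(features.region, (), np.array([]), y - zeros, zeros, fit_years)
    X = features.df.loc[list(fit_years), selected].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < len(selected):
        raise ValueError(f"rank-deficient design; collinear columns among {selected}")
    betas, *_ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
    fitted = pd.Series(X @ betas, index=list(fit_years))
    return FitResult(features.region, tuple(selected), betas, y - fitted, fitted, fit_years)


@dataclass
class DiagnosticsReport:
    """Residual diagnostics for a fitted regional model."""

    applicable: bool
    breusch_godfrey_p: float | None = None
    breusch_pagan_p: float | None = None
    vif_per_feature: dict[str, float] = field(default_factory=dict)
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "applicable": self.applicable,
            "breusch_godfrey_p": self.breusch_godfrey_p,
            "breusch_pagan_p": self.breusch_pagan_p,
            "vif_per_feature": self.vif_per_feature,
            "note": self.note,
        }


def diagnostics(fit: FitResult, features: FeatureTable) -> DiagnosticsReport:
    """Breusch-Godfrey (lag 1), studentized Breusch-Pagan, and VIFs."""
    if fit.k == 0:
        return DiagnosticsReport(False, note="not applicable: empty selection")
    if len(fit.fit_years) < fit.k + 2:
        raise ValueError("need at least K+2 residuals for diagnostics")
    years = sorted(fit.fit_years)
    X = features.df.loc[years, list(fit.selected_features)].to_numpy(dtype=float)
    y = fit.fitted.loc[years].to_numpy() + fit.residuals.loc[years].to_numpy()
    res = sm.OLS(y, X).fit()
    bg_p = float(acorr_breusch_godfrey(res, nlags=1)[1])
    bp_p = float(het_breuschpagan(res.resid, sm.add_constant(X))[1])

    vif: dict[str, float] = {}
    for j, name in enumerate(fit.selected_features):
        if fit.k == 1:
            vif[name] = 1.0
            continue
        others = np.delete(X, j, axis=1)
        aux = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2 = min(aux.rsquared, 1 - 1e-12)
        vif[name] = float(max(1.0, 1.0 / (1.0 - r2)))
    return DiagnosticsReport(True, bg_p, bp_p, vif)


def write_fit_report_json(
    fit: FitResult, diag: DiagnosticsReport, path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({"fit": fit.to_dict(), "diagnostics": diag.to_dict()}, indent=2)
    )
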