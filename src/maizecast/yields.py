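"""Yield series, log-scale detrending with AIC model choice, and retrending.

Yields are modelled on the log scale. Three trend candidates — mean
(constant), linear, quadratic in the year index — are fit by OLS over the
fit years; the one with the lowest Gaussian AIC, n*ln(SSE/n) + 2p, is
retained (ties break toward fewer parameters). Anomalies are log-yield
minus the fitted trend; retrending inverts the composition exactly, so a
detrend-retrend round trip reproduces the observed yields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TREND_ORDER = ("mean", "linear", "quadratic")
_DEGREE = {"mean": 0, "linear": 1, "quadratic": 2}


@dataclass
class YieldSeries:
    """Absolute maize yields (t/ha) for one region, one value per year."""

    region: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise ValueError("years and values must align")
        if len(np.unique(self.years)) != len(self.years):
            raise ValueError("one value per region-year required")
        if not np.all(self.values > 0):
            raise ValueError("yields must be strictly positive")

    def log(self) -> pd.Series:
        return pd.Series(np.log(self.values), index=self.years)

    def subset(self, years) -> "YieldSeries":
        mask = np.isin(self.years, list(years))
        return YieldSeries(self.region, self.years[mask], self.values[mask])


@dataclass
class TrendModel:
    """Fitted log-scale trend: the AIC-minimal of mean/linear/quadratic."""

    type: str
    coefficients: np.ndarray  # log(t/ha) per power of (year - year0)
    year0: int
    aic_per_candidate: dict[str, float]
    fit_years: tuple[int, ...]

    def predict(self, years) -> np.ndarray:
        t = np.asarray(years, dtype=float) - self.year0
        return sum(c * t**p for p, c in enumerate(self.coefficients))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "type": self.type,
                    "coefficients": list(self.coefficients),
                    "year0": self.year0,
                    "aic_per_candidate": self.aic_per_candidate,
                    "fit_years": list(self.fit_years),
                },
                indent=2,
            )
        )


def _gaussian_aic(sse: float, n: int, p: int, ss_tot: float) -> float:
    # numerically-exact fits are floored to a common tiny SSE so that float
    # dust cannot decide between them; the tie then breaks to fewer params
    floor = 1e-12 * max(ss_tot, 1.0)
    return n * np.log(max(sse, floor) / n) + 2 * p


def detrend(yields: YieldSeries, fit_years=None) -> tuple[pd.Series, TrendModel]:
    """Fit the AIC-chosen trend on ``fit_years`` and return log-scale anomalies
    for ALL years of the series plus the fitted trend model."""
    fit_years = tuple(int(y) for y in (fit_years if fit_years is not None else yields.years))
    if len(fit_years) < 4:
        raise ValueError("need at least 4 fit years to detrend")
    log_y = yields.log()
    y_fit = log_y.loc[list(fit_years)].to_numpy()
    year0 = min(fit_years)
    t_fit = np.asarray(fit_years, dtype=float) - year0

    best: tuple[str, np.ndarray] | None = None
    best_aic = np.inf
    aics: dict[str, float] = {}
    ss_tot = float(np.sum((y_fit - y_fit.mean()) ** 2))
    for name in TREND_ORDER:
        deg = _DEGREE[name]
        X = np.vander(t_fit, deg + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(X, y_fit, rcond=None)
        sse = float(np.sum((y_fit - X @ coef) ** 2))
        aic = _gaussian_aic(sse, len(fit_years), deg + 1, ss_tot)
        aics[name] = aic
        if aic < best_aic:  # strict: ties keep the simpler earlier model
            best, best_aic = (name, coef), aic
    name, coef = best
    model = TrendModel(name, np.asarray(coef), year0, aics, fit_years)
    anomalies = log_y - model.predict(log_y.index.to_numpy())
    return anomalies, model


def retrend(anomalies: pd.Series, trend: TrendModel, years=None) -> pd.Series:
    """Absolute yields (t/ha) from predicted log anomalies: exp(anomaly + trend)."""
    if years is None:
        years = anomalies.index.to_numpy()
    years = np.asarray(list(years), dtype=int)
    vals = np.exp(anomalies.loc[years].to_numpy(dtype=float) + trend.predict(years))
    return pd.Series(vals, index=years)
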