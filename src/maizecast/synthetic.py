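"""Synthetic weather, SST, and yield generator with known ground truth.

Emulates the statistical structure the forecasting pipeline assumes about
its inputs: daily rainfall from a Bernoulli-gamma occurrence/intensity
model with unimodal (Musumi-like, rains December-April) or bimodal
(Vuli + Masika) seasonality, daily temperature as a seasonal sinusoid with
AR(1) noise, monthly SST anomalies as mean-zero AR(1) series, and annual
yields generated from a known linear model on a known subset of
standardized features plus a trend and Gaussian noise on the log scale.

Every stream is seeded per (region, variable) by stable hashing of the
master seed, so adding regions or variables does not perturb existing
series and identical configurations reproduce bit-identical data.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .weather import DAYS_PER_YEAR, RegionDailyWeather, SSTSeries

SST_INDICES = ("nino34", "wp", "iod")

#: default wet-season peak day-of-year per regime; bimodal lists the Masika
#: (long rains, ~mid April) peak first and the Vuli (short rains, ~mid Nov) second
DEFAULT_PEAKS = {"unimodal": (45,), "bimodal": (105, 320)}


def _rng(seed: int, key: str) -> np.random.Generator:
    """Independent stream derived from the master seed by stable hashing."""
    return np.random.default_rng([seed, zlib.crc32(key.encode())])


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic data set.

    Defaults mirror a 10-year regional panel (harvest years 2010-2019) of
    East-African scale: ~900 mm annual rainfall, ~23 degC mean temperature
    with a small seasonal cycle, and persistent (AR1 = 0.85) SST anomalies.
    """

    n_regions: int = 8
    n_grid_cells_per_region: int = 2
    years: tuple[int, ...] = tuple(range(2010, 2020))
    regime_per_region: tuple[str, ...] | str = "alternating"
    wet_season_peak_doy: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PEAKS)
    )
    mean_annual_rain: float = 900.0
    temp_mean: float = 23.0
    temp_amplitude: float = 3.0
    temp_noise_sd: float = 1.2
    temp_ar1: float = 0.7
    diurnal_half_range: float = 5.0
    sst_ar1_coefficient: float = 0.85
    sst_innovation_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        diffs = np.diff(self.years)
        if len(self.years) < 2 or not np.all(diffs == 1):
            raise ValueError("years must be strictly increasing and contiguous")
        if abs(self.sst_ar1_coefficient) >= 1:
            raise ValueError("SST AR(1) coefficient must satisfy |phi| < 1")
        if isinstance(self.regime_per_region, str):
            if self.regime_per_region == "alternating":
                self.regime_per_region = tuple(
                    "unimodal" if i % 2 == 0 else "bimodal" for i in range(self.n_regions)
                )
            else:
                self.regime_per_region = (self.regime_per_region,) * self.n_regions
        if len(self.regime_per_region) != self.n_regions:
            raise ValueError("one regime per region required")
        for r in self.regime_per_region:
            if r not in ("unimodal", "bimodal"):
                raise ValueError(f"unknown regime {r!r}")

    @property
    def region_ids(self) -> list[str]:
        return [f"R{i:02d}" for i in range(self.n_regions)]

    @property
    def base_year(self) -> int:
        return self.years[0] - 1

    @property
    def n_span_years(self) -> int:
        return len(self.years) + 1

    def regime_of(self, region: str) -> str:
        return self.regime_per_region[self.region_ids.index(region)]


@dataclass
class SyntheticTruth:
    """Ground-truth yield model used for parameter-recovery tests."""

    true_feature_names: tuple[str, ...]
    true_betas: tuple[float, ...]  # log-yield change per standard deviation
    trend_type: str = "linear"  # mean | linear | quadratic
    trend_coefficients: tuple[float, ...] = (0.47, 0.01)  # log(t/ha) per year-power
    noise_sd: float = 0.05  # log-yield units
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_feature_names = tuple(self.true_feature_names)
        self.true_betas = tuple(float(b) for b in self.true_betas)
        if len(self.true_feature_names) > 5:
            raise ValueError("at most 5 true features allowed")
        if len(self.true_feature_names) != len(self.true_betas):
            raise ValueError("one beta per true feature required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.trend_type not in ("mean", "linear", "quadratic"):
            raise ValueError(f"unknown trend type {self.trend_type!r}")

    def trend(self, years: np.ndarray, year0: int) -> np.ndarray:
        t = np.asarray(years, dtype=float) - year0
        coefs = np.asarray(self.trend_coefficients, dtype=float)
        return sum(c * t**p for p, c in enumerate(coefs))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_feature_names": list(self.true_feature_names),
                    "true_betas": list(self.true_betas),
                    "trend_type": self.trend_type,
                    "trend_coefficients": list(self.trend_coefficients),
                    "noise_sd": self.noise_sd,
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["true_feature_names"]),
            tuple(d["true_betas"]),
            d["trend_type"],
            tuple(d["trend_coefficients"]),
            d["noise_sd"],
            d["seed"],
        )


def _seasonal_bump(doy: np.ndarray, peak: float, kappa: float) -> np.ndarray:
    """Smooth circular bump in [0, 1] peaking at ``peak`` (von Mises shape)."""
    return np.exp(kappa * (np.cos(2 * np.pi * (doy - peak) / DAYS_PER_YEAR) - 1.0))


def wet_day_probability(config: SyntheticConfig, regime: str) -> np.ndarray:
    """Daily wet-day probability over one 365-day year for the given regime."""
    doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    peaks = config.wet_season_peak_doy[regime]
    if regime == "unimodal":
        p = 0.05 + 0.60 * _seasonal_bump(doy, peaks[0], 3.0)
    else:
        masika, vuli = peaks[0], peaks[1]
        p = (
            0.05
            + 0.50 * _seasonal_bump(doy, masika, 6.0)
            + 0.35 * _seasonal_bump(doy, vuli, 8.0)
        )
    return np.clip(p, 0.0, 0.95)


def gen_region_weather(config: SyntheticConfig, region: str) -> RegionDailyWeather:
    """Daily weather for one region: all harvest years plus the preceding year.

    Precipitation follows a Bernoulli-gamma model (seasonal wet-day
    probability, gamma intensities scaled so the expected annual total is
    ``mean_annual_rain``); temperature is a seasonal sinusoid with AR(1)
    noise, with tasmax/tasmin kept strictly ordered around tas.
    """
    regime = config.regime_of(region)
    n_days = config.n_span_years * DAYS_PER_YEAR
    doy = np.arange(n_days) % DAYS_PER_YEAR + 1

    p_year = wet_day_probability(config, regime)
    p = p_year[doy - 1]
    shape = 0.9
    total_expected_wet = p_year.sum() * shape
    scale = config.mean_annual_rain / total_expected_wet if total_expected_wet > 0 else 0.0

    cells, weights = {}, {}
    raw_w = _rng(config.seed, f"{region}/weights").uniform(0.5, 1.5, config.n_grid_cells_per_region)
    for c in range(config.n_grid_cells_per_region):
        cell = f"{region}c{c}"
        rng_p = _rng(config.seed, f"{region}/{cell}/precip")
        occurrence = rng_p.random(n_days) < p
        intensity = rng_p.gamma(shape, 1.0, n_days) * scale
        precip = np.where(occurrence, intensity, 0.0)
        if config.mean_annual_rain == 0:
            precip = np.zeros(n_days)

        rng_t = _rng(config.seed, f"{region}/{cell}/temp")
        seasonal = config.temp_mean + config.temp_amplitude * np.cos(
            2 * np.pi * (doy - 15) / DAYS_PER_YEAR
        )
        eps = rng_t.normal(0.0, config.temp_noise_sd, n_days)
        noise = np.empty(n_days)
        phi = config.temp_ar1
        noise[0] = eps[0] / np.sqrt(1 - phi**2)
        for i in range(1, n_days):
            noise[i] = phi * noise[i - 1] + eps[i]
        tas = seasonal + noise
        spread_hi = np.abs(rng_t.normal(0.0, 0.8, n_days))
        spread_lo = np.abs(rng_t.normal(0.0, 0.8, n_days))
        tasmax = tas + config.diurnal_half_range + spread_hi
        tasmin = tas - config.diurnal_half_range - spread_lo

        cells[cell] = pd.DataFrame(
            {"precip": precip, "tas": tas, "tasmax": tasmax, "tasmin": tasmin}
        )
        weights[cell] = float(raw_w[c])

    return RegionDailyWeather(region, config.base_year, config.years, cells, weights)


def gen_sst_series(config: SyntheticConfig, index_name: str) -> SSTSeries:
    """Mean-zero AR(1) monthly anomaly series over the full span."""
    if index_name not in SST_INDICES:
        raise ValueError(f"unknown SST index {index_name!r}; expected one of {SST_INDICES}")
    phi = config.sst_ar1_coefficient
    n = config.n_span_years * 12
    rng = _rng(config.seed, f"sst/{index_name}")
    eps = rng.normal(0.0, config.sst_innovation_sd, n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return SSTSeries(index_name, config.base_year, x)


def gen_yields(features, truth: SyntheticTruth, region: str | None = None):
    """Absolute yields from the ground-truth linear model on standardized features.

    log-yield(t) = trend(t) + sum_k beta_k * x_k(t) + N(0, noise_sd), returned
    on the t/ha scale via exponentiation.
    """
    from .yields import YieldSeries

    if not features.standardized:
        raise ValueError("features must be standardized before yield generation")
    missing = [f for f in truth.true_feature_names if f not in features.df.columns]
    if missing:
        raise ValueError(f"true features missing from feature table: {missing}")
    region = region or features.region
    years = np.asarray(features.df.index, dtype=int)
    log_y = truth.trend(years, years.min()).astype(float)
    for name, beta in zip(truth.true_feature_names, truth.true_betas):
        log_y = log_y + beta * features.df[name].to_numpy()
    if truth.noise_sd > 0:
        rng = _rng(truth.seed, f"{region}/yield_noise")
        log_y = log_y + rng.normal(0.0, truth.noise_sd, len(years))
    return YieldSeries(region, years, np.exp(log_y))


def write_weather_csv(weathers: dict[str, RegionDailyWeather], path: str | Path) -> None:
    pd.concat([w.to_frame() for w in weathers.values()], ignore_index=True).to_csv(
        path, index=False
    )


def write_sst_csv(series: dict[str, SSTSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series.values()], ignore_index=True).to_csv(
        path, index=False
    )


def write_yields_csv(yields: dict, path: str | Path) -> None:
    rows = []
    for region, ys in yields.items():
        rows.append(
            pd.DataFrame({"region": region, "year": ys.years, "yield_t_ha": ys.values})
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
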