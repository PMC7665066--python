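"""Weather and SST predictor catalogue per region, harvest year, and phase.

For each phase (vegetative ``_v`` / reproductive ``_r``) of the 110-day
season the catalogue comprises: median daily mean/maximum/minimum
temperature (tas.median, tas.max, tas.min), the precipitation sum (Psum),
counts of days above/below 5, 10, 15 mm (pA*/pB*), counts of dry spells
longer than 5/10/15/20 days (cdd*), and exceedance counts against
region-specific long-term percentiles (tas.max99, tas.min01, precip.p99).
SST features (median, p99/p01 exceedance counts of the whole-series
percentiles) are computed over the vegetative window shifted back by the
index-specific lead time (120 d for Nino 3.4 and the West Pacific box,
30 d for the Indian Ocean Dipole) and exist only in the forecast-relevant
vegetative scope.

All predictors are standardized to zero mean and unit (sample) standard
deviation over the fit years before entering selection and regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .growing_season import SEASON_LENGTH, WET_DAY_MM, SeasonCalendar
from .weather import RegionDailyWeather, SSTSeries

PRECIP_THRESHOLDS_MM = (5.0, 10.0, 15.0)
DRY_SPELL_LENGTHS = (5, 10, 15, 20)
HIGH_PERCENTILE = 99.0
LOW_PERCENTILE = 1.0
DEFAULT_LEADS = {"nino34": 120, "wp": 120, "iod": 30}


# ---------------------------------------------------------------------------
# elementary feature operations


def long_term_percentile(values, q: float) -> float:
    """Empirical q-th percentile (linear interpolation) of a reference sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError("need at least 100 reference values for a long-term percentile")
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    return float(np.percentile(values, q))


def count_percentile_events(values, threshold: float, direction: str) -> int:
    """Strict-inequality count of days beyond a percentile threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = np.asarray(values, dtype=float)
    if direction == "above":
        return int((values > threshold).sum())
    if direction == "below":
        return int((values < threshold).sum())
    raise ValueError(f"unknown direction {direction!r}")


def count_threshold_days(precip, threshold_mm: float, direction: str) -> int:
    """Days with precipitation strictly above/below a fixed threshold."""
    return count_percentile_events(precip, threshold_mm, direction)


def count_dry_spells(precip, min_len: int) -> int:
    """Number of maximal runs of dry days (precip <= 0.1 mm) strictly longer
    than ``min_len``; runs are truncated at the phase boundaries."""
    dry = np.asarray(precip, dtype=float) <= WET_DAY_MM
    padded = np.concatenate([[False], dry, [False]]).astype(int)
    edges = np.diff(padded)
    run_lengths = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
    return int((run_lengths > min_len).sum())


# ---------------------------------------------------------------------------
# per-phase feature assembly


def longterm_thresholds(
    weather: RegionDailyWeather, calendar: SeasonCalendar, years
) -> dict[str, float]:
    """Region-specific long-term percentile thresholds over all in-season days
    of all available years (the percentile reference period)."""
    frames = [
        weather.season_slice(weather.mean, y, calendar.onset_offset, SEASON_LENGTH)
        for y in years
    ]
    pool = pd.concat(frames)
    return {
        "tasmax_p99": long_term_percentile(pool["tasmax"], HIGH_PERCENTILE),
        "tasmin_p01": long_term_percentile(pool["tasmin"], LOW_PERCENTILE),
        "precip_p99": long_term_percentile(pool["precip"], HIGH_PERCENTILE),
    }


def phase_weather_features(
    weather: RegionDailyWeather,
    calendar: SeasonCalendar,
    year: int,
    phase: str,
    thresholds: dict[str, float],
) -> dict[str, float]:
    """All weather predictors for one phase of one harvest year (suffix _v/_r)."""
    start, n_days = calendar.phase_offsets(phase)
    sub = weather.season_slice(weather.mean, year, start, n_days)
    precip = sub["precip"].to_numpy()
    out = {
        "tas.median": float(np.median(sub["tas"])),
        "tas.max": float(np.median(sub["tasmax"])),
        "tas.min": float(np.median(sub["tasmin"])),
        "Psum": float(precip.sum()),
    }
    for thr in PRECIP_THRESHOLDS_MM:
        out[f"pA{thr:g}"] = count_threshold_days(precip, thr, "above")
        out[f"pB{thr:g}"] = count_threshold_days(precip, thr, "below")
    for n in DRY_SPELL_LENGTHS:
        out[f"cdd{n}"] = count_dry_spells(precip, n)
    out["tas.max99"] = count_percentile_events(sub["tasmax"], thresholds["tasmax_p99"], "above")
    out["tas.min01"] = count_percentile_events(sub["tasmin"], thresholds["tasmin_p01"], "below")
    out["precip.p99"] = count_percentile_events(precip, thresholds["precip_p99"], "above")
    return {f"{k}_{phase}": float(v) for k, v in out.items()}


def sst_features(
    sst: SSTSeries,
    calendar: SeasonCalendar,
    year: int,
    lead_days: int,
) -> dict[str, float]:
    """SST predictors over the vegetative window shifted back by the lead time.

    The window is [onset - lead, split - lead] in continuous time; monthly
    values whose month midpoint falls inside it contribute. The p99/p01
    thresholds are percentiles of the whole multi-year series.
    """
    year_base = (year - sst.base_year) * 365
    lo = year_base + calendar.onset_offset - lead_days
    hi = year_base + calendar.split_offset - lead_days
    vals = sst.window_values(lo, hi)
    hi_thr = float(np.percentile(sst.anomaly, HIGH_PERCENTILE))
    lo_thr = float(np.percentile(sst.anomaly, LOW_PERCENTILE))
    prefix = f"{sst.index_name}_{lead_days}"
    return {
        f"{prefix}.median": float(np.median(vals)),
        f"{prefix}.p99": count_percentile_events(vals, hi_thr, "above"),
        f"{prefix}.p01": count_percentile_events(vals, lo_thr, "below"),
    }


def select_lead_time(
    sst: SSTSeries,
    calendar: SeasonCalendar,
    years,
    yield_anomalies: pd.Series,
    candidate_leads,
) -> int:
    """Lead time whose median-SST feature correlates most strongly (|Pearson r|)
    with the yield anomalies; ties go to the shorter lead."""
    years = list(years)
    if len(years) < 3:
        raise ValueError("need at least 3 years to select a lead time")
    candidates = sorted(int(c) for c in candidate_leads)
    if len(candidates) == 1:
        return candidates[0]
    y = yield_anomalies.loc[years].to_numpy(dtype=float)
    best, best_r = None, -1.0
    for lead in candidates:
        x = np.array(
            [sst_features(sst, calendar, yr, lead)[f"{sst.index_name}_{lead}.median"] for yr in years]
        )
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = abs(stats.pearsonr(x, y)[0])
        if r > best_r + 1e-12:
            best, best_r = lead, r
    if best is None:
        raise ValueError("degenerate (zero-variance) SST feature for all candidate leads")
    return best


# ---------------------------------------------------------------------------
# feature table


@dataclass
class FeatureTable:
    """Year-by-predictor matrix for one region, with phase tags and, once
    standardized, the per-column fit-set mean/sd for reuse on held-out years."""

    region: str
    df: pd.DataFrame  # index: harvest years; columns: named predictors
    phase: dict[str, str]  # column -> 'v' | 'r' | 'sst'
    units: dict[str, str] = field(default_factory=dict)
    standardized: bool = False
    std_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.df.isna().any().any():
            raise ValueError("feature table contains missing cells")

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def subset_scope(self, scope: str) -> "FeatureTable":
        """estimation: all features; forecast: vegetative + SST only."""
        if scope == "estimation":
            return self
        if scope != "forecast":
            raise ValueError(f"unknown scope {scope!r}")
        keep = [c for c in self.df.columns if self.phase[c] in ("v", "sst")]
        return replace(
            self,
            df=self.df[keep].copy(),
            phase={c: self.phase[c] for c in keep},
            units={c: u for c, u in self.units.items() if c in keep},
            std_params={c: p for c, p in self.std_params.items() if c in keep},
            zero_variance=tuple(c for c in self.zero_variance if c in keep),
        )

    def standardize(self, fit_years) -> "FeatureTable":
        """(x - mean_fit) / sd_fit applied to all years using fit-year
        statistics (sample sd); zero-sd columns are flagged, not scaled."""
        fit_years = list(fit_years)
        fit = self.df.loc[fit_years]
        out = self.df.copy().astype(float)
        params: dict[str, tuple[float, float]] = {}
        flagged = []
        for col in self.df.columns:
            mu = float(fit[col].mean())
            sd = float(fit[col].std(ddof=1))
            if sd == 0 or not np.isfinite(sd):
                flagged.append(col)
                continue
            out[col] = (out[col] - mu) / sd
            params[col] = (mu, sd)
        return replace(
            self,
            df=out,
            standardized=True,
            std_params=params,
            zero_variance=tuple(flagged),
        )

    def drop(self, cols) -> "FeatureTable":
        keep = [c for c in self.df.columns if c not in set(cols)]
        return replace(
            self,
            df=self.df[keep].copy(),
            phase={c: self.phase[c] for c in keep},
            units={c: u for c, u in self.units.items() if c in keep},
            std_params={c: p for c, p in self.std_params.items() if c in keep},
            zero_variance=tuple(c for c in self.zero_variance if c in keep),
        )

    def write_csv(self, path: str | Path) -> None:
        wide = self.df.copy()
        wide.insert(0, "region", self.region)
        wide.to_csv(path, index_label="year")

    def write_params_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "region": self.region,
                    "standardized": self.standardized,
                    "params": {c: list(p) for c, p in self.std_params.items()},
                    "zero_variance": list(self.zero_variance),
                },
                indent=2,
            )
        )


WEATHER_UNITS = {
    "tas.median": "degC",
    "tas.max": "degC",
    "tas.min": "degC",
    "Psum": "mm",
    "tas.max99": "days",
    "tas.min01": "days",
    "precip.p99": "days",
}


def build_feature_table(
    weather: RegionDailyWeather,
    calendar: SeasonCalendar,
    sst: dict[str, SSTSeries],
    years,
    leads: dict[str, int] | None = None,
) -> FeatureTable:
    """Assemble the full native-unit predictor catalogue for one region."""
    years = list(years)
    leads = leads or DEFAULT_LEADS
    thresholds = longterm_thresholds(weather, calendar, years)
    rows = []
    for year in years:
        row: dict[str, float] = {}
        for phase in ("v", "r"):
            row.update(phase_weather_features(weather, calendar, year, phase, thresholds))
        for name, series in sst.items():
            row.update(sst_features(series, calendar, year, leads[name]))
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(years, name="year"))
    phase = {}
    units = {}
    for col in df.columns:
        if col.endswith("_v"):
            phase[col] = "v"
        elif col.endswith("_r"):
            phase[col] = "r"
        else:
            phase[col] = "sst"
        stem = col[:-2] if col.endswith(("_v", "_r")) else None
        if stem in WEATHER_UNITS:
            units[col] = WEATHER_UNITS[stem]
        elif stem is not None:
            units[col] = "days" if stem.startswith(("pA", "pB", "cdd")) else ""
        else:
            units[col] = "degC" if col.endswith(".median") else "months"
    return FeatureTable(weather.region, df, phase, units)
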