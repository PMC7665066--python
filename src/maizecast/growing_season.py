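"""Rainfall-onset detection, static crop calendar, and phenological phase split.

The growing-season onset follows the three agronomic criteria of Dodd &
Jolliffe: a candidate day starts the season when (i) the 6-day window from
that day accumulates at least 25 mm of rain, (ii) the day itself and at
least two further days in the window are wet (> 0.1 mm), and (iii) the 40
days after the candidate contain no dry spell of 10 or more consecutive
days. The season ends a fixed 110 days after onset (typical Tanzanian
maize cultivars mature in 105-114 days), and is split into vegetative and
reproductive phases at the day where half the season's growing-degree-day
(GDD) sum is reached.

The calendar is static per region: onsets are detected per grid cell and
harvest year, reduced by a median over cells and then a median over years.
In bimodal (Vuli + Masika) regions the search is restricted to the Masika
window so the long-rains onset is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .weather import DAYS_PER_YEAR, RegionDailyWeather, day_index, doy_of

WET_DAY_MM = 0.1  # a day is wet if precip > 0.1 mm, dry otherwise
SEASON_LENGTH = 110
ONSET_SUM_MM = 25.0
ONSET_WINDOW_DAYS = 6
ONSET_MIN_OTHER_WET = 2
DRY_SPELL_DAYS = 10
DRY_CHECK_DAYS = 40

#: default onset search windows as (start_doy, end_doy), end inclusive; a
#: start after the end wraps into the previous calendar year. Unimodal
#: (Musumi) rains fall December-April, so the search opens 1 Nov; the
#: bimodal search covers the Masika (long rains, March-May) onset.
SEARCH_WINDOWS = {"unimodal": (305, 59), "bimodal": (32, 120)}


@dataclass(frozen=True)
class GddParams:
    """Base/cap temperatures for growing-degree-day accumulation (maize defaults)."""

    t_base: float = 10.0
    t_cap: float = 30.0

    def __post_init__(self) -> None:
        if self.t_cap <= self.t_base:
            raise ValueError("t_cap must exceed t_base")


@dataclass
class SeasonCalendar:
    """Static per-region crop calendar.

    ``onset_offset`` is the onset day counted from 1 January of the harvest
    year (0-based; negative values fall in the preceding calendar year).
    ``split_day`` is the last vegetative day in season-relative coordinates
    (day 1 = onset day), so the lead time of a within-season forecast is
    ``season_length - split_day`` days.
    """

    region: str
    regime: str
    onset_offset: int
    split_day: int
    season_length: int = SEASON_LENGTH

    def __post_init__(self) -> None:
        if not 1 <= self.split_day <= self.season_length - 1:
            raise ValueError("split_day must lie strictly inside the season")

    @property
    def onset_doy(self) -> int:
        return doy_of(self.onset_offset)

    @property
    def end_offset(self) -> int:
        return self.onset_offset + self.season_length

    @property
    def end_doy(self) -> int:
        return doy_of(self.end_offset)

    @property
    def split_offset(self) -> int:
        return self.onset_offset + self.split_day - 1

    @property
    def split_doy(self) -> int:
        return doy_of(self.split_offset)

    @property
    def lead_time_days(self) -> int:
        return self.season_length - self.split_day

    def phase_offsets(self, phase: str) -> tuple[int, int]:
        """(start_offset, n_days) of a phase relative to 1 Jan of the harvest year."""
        if phase == "v":
            return self.onset_offset, self.split_day
        if phase == "r":
            return self.onset_offset + self.split_day, self.season_length - self.split_day
        raise ValueError(f"unknown phase {phase!r}")


def median_low(values) -> int:
    """Median with a deterministic tie rule: for an even count, the lower of
    the two central values, rounded to an integer day."""
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValueError("median of empty set")
    return int(round(arr[(arr.size - 1) // 2]))


def daily_gdd(tas, params: GddParams) -> np.ndarray:
    """Growing degree days: max(0, min(tas, t_cap) - t_base)."""
    return np.maximum(0.0, np.minimum(np.asarray(tas, dtype=float), params.t_cap) - params.t_base)


def detect_onset(precip: np.ndarray, search_window: tuple[int, int]) -> int | None:
    """First day in ``search_window`` (inclusive absolute indices into
    ``precip``) satisfying the three onset criteria, or None.

    Vectorized: 6-day sums via sliding windows and the dry-spell check via
    run lengths of dry days; both candidate-day criteria and the 40-day
    follow-up check must hold.
    """
    lo, hi = search_window
    precip = np.asarray(precip, dtype=float)
    if lo < 0 or hi < lo:
        raise ValueError("invalid search window")
    if len(precip) < hi + DRY_CHECK_DAYS + ONSET_WINDOW_DAYS:
        raise ValueError("window not covered")

    wet = precip > WET_DAY_MM
    # run length of consecutive dry days ending at each index
    dry_run = np.zeros(len(precip), dtype=int)
    run = 0
    for i, w in enumerate(wet):
        run = 0 if w else run + 1
        dry_run[i] = run
    # a dry spell of >= 10 days lies fully inside [d+1, d+40] iff some index
    # i in [d+10, d+40] has dry_run[i] >= 10
    spell_end = (dry_run >= DRY_SPELL_DAYS).astype(int)
    cum = np.concatenate([[0], np.cumsum(spell_end)])

    window6 = np.lib.stride_tricks.sliding_window_view(precip, ONSET_WINDOW_DAYS)
    sums6 = window6.sum(axis=1)
    wet6 = window6 > WET_DAY_MM

    for d in range(lo, hi + 1):
        if sums6[d] < ONSET_SUM_MM:
            continue
        if not wet6[d, 0] or wet6[d, 1:].sum() < ONSET_MIN_OTHER_WET:
            continue
        a, b = d + DRY_SPELL_DAYS, d + DRY_CHECK_DAYS
        if cum[b + 1] - cum[a] > 0:
            continue
        return d
    return None


def window_offsets(regime: str, windows: dict[str, tuple[int, int]] | None = None) -> tuple[int, int]:
    """Search window as day offsets relative to 1 Jan of the harvest year."""
    start_doy, end_doy = (windows or SEARCH_WINDOWS)[regime]
    if start_doy > end_doy:  # wraps into the previous calendar year
        return start_doy - 1 - DAYS_PER_YEAR, end_doy - 1
    return start_doy - 1, end_doy - 1


def detect_yearly_onsets(
    weather: RegionDailyWeather,
    regime: str,
    years,
    windows: dict[str, tuple[int, int]] | None = None,
) -> dict[int, dict[str, int]]:
    """Per-year, per-cell onset offsets (relative to 1 Jan of the harvest year)."""
    weather.check_covers(years)
    w0, w1 = window_offsets(regime, windows)
    out: dict[int, dict[str, int]] = {}
    for year in years:
        base = day_index(year, 1, weather.base_year)
        per_cell = {}
        for cell, df in weather.cells.items():
            found = detect_onset(df["precip"].to_numpy(), (base + w0, base + w1))
            if found is not None:
                per_cell[cell] = found - base
        if per_cell:
            out[year] = per_cell
    return out


def gdd_split(tas_season: np.ndarray, params: GddParams) -> int:
    """First season day s (1-based) at which cumulative GDD reaches half the
    full-season total."""
    gdd = daily_gdd(tas_season, params)
    total = gdd.sum()
    if total <= 0:
        raise ValueError("no thermal accumulation")
    cum = np.cumsum(gdd)
    return int(np.searchsorted(cum, 0.5 * total) + 1)


def split_phases(
    weather: RegionDailyWeather,
    onset_offset: int,
    params: GddParams,
    year: int,
) -> int:
    """Season-relative vegetative/reproductive split day for one harvest year,
    computed on the region-aggregated temperature."""
    season = weather.season_slice(weather.mean, year, onset_offset, SEASON_LENGTH)
    return gdd_split(season["tas"].to_numpy(), params)


def build_calendar(
    weather: RegionDailyWeather,
    regime: str,
    years,
    gdd_params: GddParams = GddParams(),
    windows: dict[str, tuple[int, int]] | None = None,
) -> SeasonCalendar:
    """Static calendar: median over grid cells within each year, then median
    over years, of the detected onsets; split day is the median over years of
    the per-year GDD split at the static onset."""
    onsets = detect_yearly_onsets(weather, regime, years, windows)
    if not onsets:
        raise ValueError("no growing season detected")
    yearly = [median_low(list(cells.values())) for cells in onsets.values()]
    onset_offset = median_low(yearly)

    splits = []
    for year in years:
        try:
            splits.append(split_phases(weather, onset_offset, gdd_params, year))
        except ValueError:
            continue
    if not splits:
        raise ValueError("no thermal accumulation in any season")
    split_day = min(median_low(splits), SEASON_LENGTH - 1)
    return SeasonCalendar(weather.region, regime, onset_offset, split_day)


def write_calendars_csv(calendars: dict[str, SeasonCalendar], path: str | Path) -> None:
    rows = [
        {
            "region": c.region,
            "regime": c.regime,
            "onset_doy": c.onset_doy,
            "onset_offset": c.onset_offset,
            "split_day": c.split_day,
            "split_doy": c.split_doy,
            "end_doy": c.end_doy,
            "lead_time_days": c.lead_time_days,
        }
        for c in calendars.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calendars_csv(path: str | Path) -> dict[str, SeasonCalendar]:
    frame = pd.read_csv(path)
    return {
        str(r.region): SeasonCalendar(
            str(r.region), str(r.regime), int(r.onset_offset), int(r.split_day)
        )
        for r in frame.itertuples()
    }
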