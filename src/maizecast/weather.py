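"""In-memory containers for daily regional weather and monthly SST anomalies.

All synthetic series live on a simplified 365-day calendar (no leap days).
Days are addressed by an absolute, continuous day index counted from
1 January of ``base_year``; day-of-year values are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
#: month lengths on the 365-day calendar (February fixed at 28 days)
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)[:-1]])


def day_index(year: int, doy: int, base_year: int) -> int:
    """Absolute day index of ``doy`` (1-based) in ``year``."""
    return (year - base_year) * DAYS_PER_YEAR + doy - 1


def doy_of(offset: int) -> int:
    """1-based day-of-year of a day offset relative to some 1 January."""
    return int(offset) % DAYS_PER_YEAR + 1


@dataclass
class RegionDailyWeather:
    """Continuous daily precipitation/temperature series for one region.

    Holds one series per grid cell together with area weights; feature
    computation uses the area-weighted mean across cells, onset detection
    runs per cell.
    """

    region: str
    base_year: int
    years: tuple[int, ...]  # harvest years (base_year is the lead-in year)
    cells: dict[str, pd.DataFrame]  # columns: precip, tas, tasmax, tasmin
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("at least one grid cell required")
        lengths = {len(df) for df in self.cells.values()}
        if len(lengths) != 1:
            raise ValueError("all cells must cover the same daily span")
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            self.weights = {k: w / total for k, w in self.weights.items()}

    @property
    def n_days(self) -> int:
        return len(next(iter(self.cells.values())))

    def check_covers(self, years: list[int] | tuple[int, ...]) -> None:
        """Require the daily span to cover all ``years`` plus the preceding year."""
        first_needed = min(years) - 1
        last_needed = max(years)
        have_last = self.base_year + self.n_days // DAYS_PER_YEAR - 1
        if self.base_year > first_needed or have_last < last_needed:
            raise ValueError(
                f"insufficient span: have {self.base_year}..{have_last}, "
                f"need {first_needed}..{last_needed}"
            )

    @cached_property
    def mean(self) -> pd.DataFrame:
        """Area-weighted mean across grid cells, indexed by absolute day."""
        acc = None
        for cell, df in self.cells.items():
            contrib = df[["precip", "tas", "tasmax", "tasmin"]] * self.weights[cell]
            acc = contrib if acc is None else acc + contrib
        return acc

    def season_slice(self, frame: pd.DataFrame, year: int, start_offset: int, n_days: int) -> pd.DataFrame:
        """``n_days`` rows starting at ``start_offset`` relative to 1 Jan of ``year``."""
        i0 = day_index(year, 1, self.base_year) + start_offset
        if i0 < 0 or i0 + n_days > len(frame):
            raise ValueError("window not covered")
        return frame.iloc[i0 : i0 + n_days]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame (one row per cell-day) for CSV export."""
        rows = []
        for cell, df in self.cells.items():
            n = len(df)
            idx = np.arange(n)
            rows.append(
                pd.DataFrame(
                    {
                        "region": self.region,
                        "year": self.base_year + idx // DAYS_PER_YEAR,
                        "doy": idx % DAYS_PER_YEAR + 1,
                        "cell_id": cell,
                        "area_weight": self.weights[cell],
                        "precip": df["precip"].to_numpy(),
                        "tas": df["tas"].to_numpy(),
                        "tasmax": df["tasmax"].to_numpy(),
                        "tasmin": df["tasmin"].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, years: tuple[int, ...]) -> "RegionDailyWeather":
        region = str(frame["region"].iloc[0])
        base_year = int(frame["year"].min())
        cells, weights = {}, {}
        for cell, sub in frame.groupby("cell_id", sort=True):
            sub = sub.sort_values(["year", "doy"]).reset_index(drop=True)
            cells[str(cell)] = sub[["precip", "tas", "tasmax", "tasmin"]].copy()
            weights[str(cell)] = float(sub["area_weight"].iloc[0])
        return cls(region, base_year, tuple(years), cells, weights)

    @classmethod
    def read_csv(cls, path: str | Path, years: tuple[int, ...]) -> "RegionDailyWeather":
        return cls.from_frame(pd.read_csv(path), years)


@dataclass
class SSTSeries:
    """Monthly SST anomaly series for one ocean index (nino34 | wp | iod)."""

    index_name: str
    base_year: int
    anomaly: np.ndarray  # one value per month from January of base_year

    def __post_init__(self) -> None:
        self.anomaly = np.asarray(self.anomaly, dtype=float)
        if not np.all(np.isfinite(self.anomaly)):
            raise ValueError("SST anomalies must be finite")

    @property
    def n_months(self) -> int:
        return len(self.anomaly)

    def month_mid_offsets(self) -> np.ndarray:
        """Day offset (relative to 1 Jan of base_year) of each month's midpoint."""
        k = np.arange(self.n_months)
        return (k // 12) * DAYS_PER_YEAR + MONTH_STARTS[k % 12] + MONTH_LENGTHS[k % 12] / 2.0

    def window_values(self, lo: float, hi: float) -> np.ndarray:
        """Monthly anomalies whose month midpoint lies in ``[lo, hi]`` (day offsets
        relative to 1 Jan of base_year)."""
        mids = self.month_mid_offsets()
        mask = (mids >= lo) & (mids <= hi)
        if not mask.any():
            raise ValueError("window outside series")
        return self.anomaly[mask]

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(self.n_months)
        return pd.DataFrame(
            {
                "index": self.index_name,
                "year": self.base_year + k // 12,
                "month": k % 12 + 1,
                "anomaly": self.anomaly,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SSTSeries":
        frame = frame.sort_values(["year", "month"]).reset_index(drop=True)
        return cls(str(frame["index"].iloc[0]), int(frame["year"].min()), frame["anomaly"].to_numpy())
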