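"""Daily climate forcing container and calendar helpers.

A 365-day no-leap calendar is used throughout: simulated years all have the
same day-of-year axis, which keeps day-of-year climatologies (drought
percentiles, seasonal curves) exact.  The dry season runs from mid-December
(DOY >= 349) through April (DOY <= 120).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DAYS_PER_YEAR", "DRY_SEASON_START_DOY", "DRY_SEASON_END_DOY",
           "ClimateForcing", "census_intervals"]

DAYS_PER_YEAR = 365
DRY_SEASON_START_DOY = 349  # mid-December
DRY_SEASON_END_DOY = 120    # end of April


@dataclass
class ClimateForcing:
    """Daily precipitation and atmospheric demand series.

    Attributes
    ----------
    precip : ndarray, mm d-1
    vpd : ndarray, kPa
    drought_years : tuple of int
        Indices (0-based year within the series) generated as drought years.
    """

    precip: np.ndarray
    vpd: np.ndarray
    drought_years: tuple = ()
    lai: np.ndarray | None = None  # optional seasonal leaf-area curve in [0, 1]

    def __post_init__(self):
        self.precip = np.asarray(self.precip, dtype=float)
        self.vpd = np.asarray(self.vpd, dtype=float)
        if self.precip.shape != self.vpd.shape or self.precip.ndim != 1:
            raise ValueError("precip and vpd must be 1-D series of equal length")
        if self.precip.size % DAYS_PER_YEAR != 0:
            raise ValueError(f"series length must be a multiple of {DAYS_PER_YEAR}")
        if np.any(self.precip < 0) or np.any(self.vpd < 0):
            raise ValueError("precipitation and VPD must be non-negative")

    @property
    def n_days(self) -> int:
        return self.precip.size

    @property
    def n_years(self) -> int:
        return self.n_days // DAYS_PER_YEAR

    @property
    def doy(self) -> np.ndarray:
        """1-based day of year for every day of the series."""
        return np.tile(np.arange(1, DAYS_PER_YEAR + 1), self.n_years)

    @property
    def year_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_years), DAYS_PER_YEAR)

    @property
    def dry_season_mask(self) -> np.ndarray:
        d = self.doy
        return (d >= DRY_SEASON_START_DOY) | (d <= DRY_SEASON_END_DOY)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year_index,
                "doy": self.doy,
                "precip_mm": self.precip,
                "vpd_kpa": self.vpd,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClimateForcing":
        return cls(df["precip_mm"].to_numpy(), df["vpd_kpa"].to_numpy())


def census_intervals(n_years: int, interval_years: int = 5):
    """Half-open day index ranges [(start, stop), ...] for each census interval.

    Only whole intervals fully covered by the forcing are returned.
    """
    if interval_years < 1:
        raise ValueError("interval_years must be >= 1")
    n_int = n_years // interval_years
    step = interval_years * DAYS_PER_YEAR
    return [(i * step, (i + 1) * step) for i in range(n_int)]
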