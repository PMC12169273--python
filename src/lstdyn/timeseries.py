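"""Ten-day composite time series for a single pixel.

The whole package works on a fixed intra-annual sampling of 36 composite
steps per year (three per calendar month).  Continuous time for step ``s``
of year ``y`` is ``y + (s + 0.5) / 36`` — i.e. the midpoint convention — and
one step corresponds to 365/36 ≈ 10.14 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STEPS_PER_YEAR = 36
DAYS_PER_STEP = 365.0 / STEPS_PER_YEAR
STEPS_PER_MONTH = 3


@dataclass
class TimeSeries10d:
    """One pixel's 10-day composite series (LST in K, albedo, or ET in mm/10 d).

    Parameters
    ----------
    start_year : int
        Calendar year of the first composite step.
    values : ndarray
        Observations; missing steps are NaN.  Length must be a whole number
        of years (36 steps per year).
    """

    start_year: int
    values: np.ndarray
    steps_per_year: int = STEPS_PER_YEAR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.values.size % self.steps_per_year != 0:
            raise ValueError(
                f"series length {self.values.size} is not a whole number of "
                f"{self.steps_per_year}-step years"
            )
        if self.n_years < 2:
            raise ValueError("series must span at least 2 years")

    @property
    def n_steps(self) -> int:
        return self.values.size

    @property
    def n_years(self) -> int:
        return self.values.size // self.steps_per_year

    @property
    def end_year(self) -> int:
        """Last (inclusive) calendar year covered by the series."""
        return self.start_year + self.n_years - 1

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the observation is missing."""
        return ~np.isfinite(self.values)

    @property
    def time_years(self) -> np.ndarray:
        """Continuous decimal-year time at each step (midpoint convention)."""
        t = np.arange(self.n_steps, dtype=float)
        return self.start_year + (t + 0.5) / self.steps_per_year

    def year_slice(self, year: int) -> slice:
        """Step slice covering calendar ``year``."""
        if not self.start_year <= year <= self.end_year:
            raise ValueError(f"year {year} outside series span")
        i = (year - self.start_year) * self.steps_per_year
        return slice(i, i + self.steps_per_year)

    def step_to_year(self, step: int) -> int:
        """Calendar year containing global step index ``step``."""
        return self.start_year + int(step) // self.steps_per_year

    def require_coverage(self, min_years: float = 2.0) -> None:
        """Raise if fewer than ``min_years`` worth of steps are non-missing."""
        n_ok = int(np.isfinite(self.values).sum())
        if n_ok < min_years * self.steps_per_year:
            raise ValueError(
                f"only {n_ok} non-missing steps; need at least "
                f"{min_years} years of coverage"
            )
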