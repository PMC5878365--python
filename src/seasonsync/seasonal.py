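"""Percentage deviation from baseline and calendar-month seasonal profiles.

Once the linear aging baseline is removed, the residual structure of a monthly
outcome series is expressed as the percentage deviation from the fitted line,

    dev_t = 100 * (value_t - fitted_t) / fitted_t,

and the yearly seasonal variation trend is the 12-vector of per-calendar-month
means of these deviations across years (with the across-years sample SD).
Percentage deviations are scale-free, so profiles from subgroups of different
sizes are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ._calendar import add_months
from .aggregate import MonthlySeries
from .errors import DegenerateBaselineError, ShapeError
from .trend import TrendFit


@dataclass
class DeviationSeries:
    subgroup: str
    outcome: str
    start: Tuple[int, int]
    values: np.ndarray  # percent units, aligned to the source series months


@dataclass
class SeasonalProfile:
    """Mean (and SD) percentage deviation by calendar month for one subgroup."""

    zone: str
    mean_dev: np.ndarray  # length 12, percent, index 0 = January
    sd_dev: np.ndarray  # length 12, percent, sample SD across years
    n_years: int

    def __post_init__(self) -> None:
        self.mean_dev = np.asarray(self.mean_dev, dtype=float)
        self.sd_dev = np.asarray(self.sd_dev, dtype=float)
        if self.mean_dev.shape != (12,) or self.sd_dev.shape != (12,):
            raise ShapeError("seasonal profile must have exactly 12 months")
        if np.nanmin(self.sd_dev) < 0:
            raise ShapeError("sd_dev must be >= 0")


def percent_deviation(series: MonthlySeries, fit: TrendFit) -> DeviationSeries:
    """100 * (observed - fitted) / fitted at each month of the series.

    A fitted baseline at or below eps = 1e-9 * mean(fitted) makes the
    percentage unstable and raises a degenerate-baseline error naming the
    offending month rather than silently dropping it.
    """
    y = np.asarray(series.values, dtype=float)
    f = np.asarray(fit.fitted, dtype=float)
    if y.shape != f.shape:
        raise ShapeError("fit was not computed from this series (length mismatch)")
    eps = 1e-9 * float(np.mean(f))
    bad = np.nonzero(f <= eps)[0]
    if bad.size:
        month = add_months(series.start, int(bad[0]))
        raise DegenerateBaselineError(
            f"fitted baseline <= {eps:g} at month {month[0]}-{month[1]:02d}"
        )
    return DeviationSeries(series.subgroup, series.outcome, series.start, 100.0 * (y - f) / f)


def seasonal_profile(devs: DeviationSeries) -> SeasonalProfile:
    """Average deviations by calendar month across years.

    Requires the series to span a whole number of years >= 2 so every calendar
    month has the same number of observations and the sample SD (ddof=1) is
    defined.
    """
    v = np.asarray(devs.values, dtype=float)
    n = len(v)
    if n % 12 != 0 or n // 12 < 2:
        raise ShapeError(
            f"series must span an integer number of years >= 2, got {n} months"
        )
    months = np.array([add_months(devs.start, i)[1] for i in range(n)])
    mean_dev = np.empty(12)
    sd_dev = np.empty(12)
    for m in range(1, 13):
        obs = v[months == m]
        mean_dev[m - 1] = obs.mean()
        sd_dev[m - 1] = obs.std(ddof=1)
    return SeasonalProfile(devs.subgroup, mean_dev, sd_dev, n // 12)


def peak_deviation(profile: SeasonalProfile) -> Tuple[float, float, int]:
    """Largest absolute mean deviation: (peak %, SD at that month, month 1-12).

    The SD is the across-years sample SD at the peak calendar month; ties are
    broken by the earliest calendar month.
    """
    mags = np.abs(profile.mean_dev)
    idx = int(np.argmax(mags))  # argmax returns the first maximum
    return float(mags[idx]), float(profile.sd_dev[idx]), idx + 1
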