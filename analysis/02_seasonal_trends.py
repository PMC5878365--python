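"""Estimate per-zone seasonal variation trends.

Sums admissions and LOS per calendar month for each climate zone, removes the
linear aging baseline by OLS on the 36-month index, converts to percentage
deviation from baseline, and averages by calendar month across the three
years.  Writes monthly_series.csv, trend_fits.csv and seasonal_profile.csv;
prints each zone's baseline fit and peak seasonal deviation.
"""

from pathlib import Path

import pandas as pd

from seasonsync import (
    fit_linear_trend,
    monthly_series,
    peak_deviation,
    percent_deviation,
    seasonal_profile,
)
from seasonsync._calendar import add_months
from seasonsync.io_cli import read_admissions, read_patients

RESULTS = Path(__file__).resolve().parent.parent / "results"
WINDOW = ((2010, 1), 36)


def main() -> None:
    patients = read_patients(RESULTS / "patients.csv")
    records = read_admissions(RESULTS / "admissions.csv")
    zones = sorted({p.zone for p in patients})

    series_rows, fit_rows, prof_rows = [], [], []
    for zone in zones:
        for outcome in ("admissions", "los"):
            s = monthly_series(records, patients, outcome, WINDOW, subgroup=zone)
            fit = fit_linear_trend(s)
            for i, v in enumerate(s.values):
                y, m = add_months(s.start, i)
                series_rows.append((zone, outcome, y, m, v))
            fit_rows.append((zone, outcome, fit.slope, fit.intercept, fit.r2,
                             fit.adj_r2, fit.rss, fit.rmse))
            if outcome == "los":
                prof = seasonal_profile(percent_deviation(s, fit))
                for m in range(12):
                    prof_rows.append((zone, m + 1, prof.mean_dev[m], prof.sd_dev[m]))
                peak, sd, month = peak_deviation(prof)
                print(f"{zone}: LOS baseline slope {fit.slope:+.2f}/month "
                      f"(R2 {fit.r2:.2f}); peak seasonal deviation "
                      f"{peak:.1f}% (SD {sd:.1f}%) at calendar month {month}")

    pd.DataFrame(series_rows,
                 columns=["subgroup", "outcome", "year", "month", "value"]
                 ).to_csv(RESULTS / "monthly_series.csv", index=False)
    pd.DataFrame(fit_rows,
                 columns=["subgroup", "outcome", "slope", "intercept", "r2",
                          "adj_r2", "rss", "rmse"]
                 ).to_csv(RESULTS / "trend_fits.csv", index=False)
    pd.DataFrame(prof_rows,
                 columns=["zone", "month", "mean_dev_pct", "sd_dev_pct"]
                 ).to_csv(RESULTS / "seasonal_profile.csv", index=False)
    print(f"wrote monthly_series.csv, trend_fits.csv, seasonal_profile.csv to {RESULTS}")


if __name__ == "__main__":
    main()
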