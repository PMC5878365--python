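"""Linear baseline ("aging") trend for a monthly outcome series.

A chronically ill cohort's monthly admission and LOS totals drift upward over
time; the baseline is an ordinary least squares line of the monthly sums on
the month index t = 1..n.  Diagnostics follow standard OLS conventions and
the 95% prediction interval is the classical new-observation interval
(t-quantile with n-2 df, including the leverage term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .aggregate import MonthlySeries
from .errors import InsufficientDataError


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    rss: float
    rmse: float  # residual standard error, sqrt(RSS / (n-2))
    fitted: np.ndarray
    pred_lower: np.ndarray
    pred_upper: np.ndarray

    def __len__(self) -> int:
        return len(self.fitted)


def fit_linear_trend(series: MonthlySeries) -> TrendFit:
    """OLS of the series values on month index 1..n, with 95% prediction bounds.

    The intercept refers to month 0 (one month before the window starts).
    Requires n >= 3 so the prediction interval's n-2 df are positive.
    """
    y = np.asarray(series.values, dtype=float)
    n = len(y)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 months to fit a trend, got {n}")
    t = np.arange(1, n + 1, dtype=float)
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    pred = res.get_prediction(X)
    bounds = pred.conf_int(obs=True, alpha=0.05)
    # a zero-residual fit (e.g. constant or exactly linear series) has R^2 = 1
    # by convention; statsmodels returns 0/0 when the total SS is also zero
    if res.ssr <= 1e-12 * max(1.0, float(y @ y)):
        r2 = adj_r2 = 1.0
    else:
        r2, adj_r2 = float(res.rsquared), float(res.rsquared_adj)
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=r2,
        adj_r2=adj_r2,
        rss=float(res.ssr),
        rmse=float(np.sqrt(res.ssr / (n - 2))),
        fitted=np.asarray(res.fittedvalues),
        pred_lower=bounds[:, 0],
        pred_upper=bounds[:, 1],
    )
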