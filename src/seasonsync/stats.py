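"""Descriptive seasonal summaries and significance tests.

Covers the between-season comparisons (Wilcoxon rank sum for skewed monthly
aggregates, pooled two-sample t for symmetric ones), the printed-precision
share and LOS-per-admission tables, and the per-patient LOS-vs-admissions
regression.

The Wilcoxon rank-sum test uses the exact null distribution of the rank sum
for combined n <= 20 (a shift-algorithm count over doubled midranks, valid
under ties) and the normal approximation with tie and continuity corrections
otherwise; two-sided p-values are 2*min(lower tail, upper tail), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import DegenerateVarianceError, InsufficientDataError
from .synthetic_cohort import AdmissionRecord, Patient

EXACT_N_MAX = 20  # combined sample size up to which the exact null is used


@dataclass
class SeasonComparison:
    pair: Tuple[str, str]
    statistic: float
    p_value: float
    test_name: str


def _exact_ranksum_p(doubled_ranks: np.ndarray, na: int, w2: int) -> float:
    """Exact two-sided p for rank sum via subset-sum counting.

    doubled_ranks: 2*midranks (integers even under ties); w2 = 2*W_observed.
    Counts, for every subset of size na of the pooled doubled ranks, the
    distribution of their sum.
    """
    total = int(doubled_ranks.sum())
    ways = np.zeros((na + 1, total + 1))
    ways[0, 0] = 1.0
    for d in doubled_ranks:
        d = int(d)
        for k in range(na, 0, -1):
            ways[k, d:] += ways[k - 1, : total + 1 - d]
    dist = ways[na]
    n_subsets = dist.sum()
    lower = dist[: w2 + 1].sum() / n_subsets
    upper = dist[w2:].sum() / n_subsets
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_rank_sum(
    sample_a: Sequence[float], sample_b: Sequence[float], pair: Tuple[str, str] = ("A", "B")
) -> SeasonComparison:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    Exact null distribution (ties handled via midranks) for combined n <= 20;
    normal approximation with tie correction and continuity correction beyond.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    n, na, nb = pooled.size, a.size, b.size
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[:na].sum())

    if n <= EXACT_N_MAX:
        doubled = np.rint(2.0 * ranks).astype(int)
        p = _exact_ranksum_p(doubled, na, int(round(2.0 * w)))
        return SeasonComparison(pair, w, p, "wilcoxon_rank_sum")

    mu = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return SeasonComparison(pair, w, 1.0, "wilcoxon_rank_sum")
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * scipy.stats.norm.sf(abs(z))))
    return SeasonComparison(pair, w, p, "wilcoxon_rank_sum")


def two_sample_t(
    sample_a: Sequence[float], sample_b: Sequence[float], pair: Tuple[str, str] = ("A", "B")
) -> SeasonComparison:
    """Two-sided pooled-variance t test."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    df = a.size + b.size - 2
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / df
    if pooled_var <= 0:
        if np.isclose(a.mean(), b.mean()):
            return SeasonComparison(pair, 0.0, 1.0, "t_test")
        raise DegenerateVarianceError("zero pooled variance with unequal means")
    se = np.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size))
    t = float((a.mean() - b.mean()) / se)
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return SeasonComparison(pair, t, p, "t_test")


def season_shares(counts: Mapping[str, float], decimals: int = 1) -> Dict[str, float]:
    """Percentage share of each season's count in the total, rounded for report."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise InsufficientDataError("season counts sum to zero")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


def los_per_admission(
    admissions: Mapping[str, float], los_totals: Mapping[str, float]
) -> Dict[str, float]:
    """Mean LOS per admission by season, rounded to 2 decimals for report output.

    Seasons with zero admissions are flagged as NaN rather than silently
    dropped.
    """
    out: Dict[str, float] = {}
    for season, n_adm in admissions.items():
        if n_adm <= 0:
            out[season] = float("nan")
            continue
        out[season] = round(float(los_totals[season]) / float(n_adm), 2)
    return out


def patient_totals(
    records: Iterable[AdmissionRecord], patients: Sequence[Patient]
) -> pd.DataFrame:
    """Per-patient total admissions and total LOS days (zero-filled)."""
    base = pd.DataFrame({"patient_id": [p.patient_id for p in patients]})
    rows = pd.DataFrame(
        [(r.patient_id, r.los_days) for r in records], columns=["patient_id", "los"]
    )
    if rows.empty:
        base["admissions"] = 0
        base["los"] = 0
        return base
    agg = rows.groupby("patient_id").agg(admissions=("los", "size"), los=("los", "sum"))
    out = base.merge(agg, how="left", on="patient_id").fillna(0)
    return out.astype({"admissions": int, "los": int})


@dataclass
class LosAdmissionsFit:
    slope: float  # mean incremental LOS days per additional admission
    intercept: float
    r2: float
    correlation: float  # Pearson r between totals
    n_patients: int


def los_admissions_regression(totals: pd.DataFrame) -> LosAdmissionsFit:
    """OLS of per-patient total LOS on total admissions, with Pearson r.

    In simple regression r^2 equals the squared Pearson correlation; the slope
    estimates the mean LOS contributed per admission.
    """
    x = totals["admissions"].to_numpy(dtype=float)
    y = totals["los"].to_numpy(dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need >= 3 patients")
    if np.var(x) == 0:
        raise DegenerateVarianceError("admission totals have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r = float(np.corrcoef(x, y)[0, 1])
    return LosAdmissionsFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        correlation=r,
        n_patients=int(x.size),
    )
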