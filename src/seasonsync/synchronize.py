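"""Commencement-synchronized seasonal profile.

When a pre/post intervention is rolled out to patients over many months, the
seasonal deviation each patient experiences i months after their own
commencement depends on their commencement calendar month.  The synchronized
profile S_p(i) is the expected percentage deviation at month i after
commencement, pooled over all patients:

    S_p(i) = ( sum over patients k monitored at month i of
               P_{zone(k)}[ ((c_k + i - 2) mod 12) + 1 ] ) / n_at_month(i)

where c_k is patient k's commencement calendar month and P_z the zone's
seasonal profile.  Heterogeneous commencement months average seasonal peaks
and troughs against each other, so a well-spread recruitment schedule
attenuates the seasonal confound in pre/post outcome comparisons.

Each patient is weighted equally; patients monitored fewer than i months drop
out of the denominator at month i.  Month rotation is modular on the 12-month
yearly profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, EmptyProfileError
from .seasonal import SeasonalProfile


@dataclass(frozen=True)
class ScheduleEntry:
    """One test patient's zone, commencement calendar month, follow-up length."""

    zone: str
    commencement_month: int  # calendar month 1..12
    months_monitored: int = 12

    def __post_init__(self) -> None:
        if not 1 <= self.commencement_month <= 12:
            raise ConfigurationError("commencement_month must be in 1..12")
        if self.months_monitored < 1:
            raise ConfigurationError("months_monitored must be >= 1")


RecruitmentSchedule = Sequence[ScheduleEntry]


@dataclass
class SynchronizedProfile:
    sync_dev: np.ndarray  # percent, months 1..12 after commencement; NaN if undefined
    n_at_month: np.ndarray  # patients contributing at each month
    contributions: List[np.ndarray]  # per-month per-patient profile values


def synchronized_profile(
    profiles: Mapping[str, SeasonalProfile],
    schedule: RecruitmentSchedule,
) -> SynchronizedProfile:
    """Pool zone seasonal profiles over a heterogeneous recruitment schedule.

    A month with no monitored patient is NaN (undefined), never 0.
    """
    for entry in schedule:
        if entry.zone not in profiles:
            raise ConfigurationError(f"no seasonal profile for zone {entry.zone!r}")
    sync = np.full(12, np.nan)
    n_at = np.zeros(12, dtype=int)
    contributions: List[np.ndarray] = []
    for i in range(1, 13):
        vals = [
            profiles[e.zone].mean_dev[(e.commencement_month + i - 2) % 12]
            for e in schedule
            if e.months_monitored >= i
        ]
        arr = np.asarray(vals, dtype=float)
        contributions.append(arr)
        n_at[i - 1] = len(arr)
        if len(arr):
            sync[i - 1] = arr.mean()
    return SynchronizedProfile(sync, n_at, contributions)


def max_sync_deviation(sp: SynchronizedProfile) -> Tuple[float, float]:
    """Peak |synchronized deviation| and the per-patient contribution SD there.

    The SD (ddof=1) is across the individual patient profile values pooled at
    the argmax month; NaN when only one patient contributes.
    """
    defined = np.nonzero(sp.n_at_month > 0)[0]
    if defined.size == 0:
        raise EmptyProfileError("synchronized profile has no defined month")
    mags = np.abs(sp.sync_dev[defined])
    idx = int(defined[np.argmax(mags)])
    contrib = sp.contributions[idx]
    sd = float(np.std(contrib, ddof=1)) if len(contrib) > 1 else float("nan")
    return float(abs(sp.sync_dev[idx])), sd
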