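"""Closed-form calendar-month arithmetic.

Months are (year, month) pairs with month in 1..12; all arithmetic is on the
serial index year*12 + (month-1), so no date library is needed for the
month-level contracts.  Admission dates themselves are ``datetime.date``.
"""

from __future__ import annotations

import calendar
import datetime as dt
from typing import Iterator, Tuple

Month = Tuple[int, int]


def _check(month: Month) -> Month:
    y, m = month
    if not 1 <= m <= 12:
        raise ValueError(f"calendar month must be in 1..12, got {m}")
    return int(y), int(m)


def month_serial(month: Month) -> int:
    y, m = _check(month)
    return y * 12 + (m - 1)


def add_months(month: Month, k: int) -> Month:
    s = month_serial(month) + int(k)
    return s // 12, s % 12 + 1


def month_diff(a: Month, b: Month) -> int:
    """Number of months from a to b (b - a)."""
    return month_serial(b) - month_serial(a)


def month_range(start: Month, n: int) -> Iterator[Month]:
    for i in range(int(n)):
        yield add_months(start, i)


def month_of_date(d: dt.date) -> Month:
    return d.year, d.month


def days_in_month(month: Month) -> int:
    y, m = _check(month)
    return calendar.monthrange(y, m)[1]


def in_window(month: Month, start: Month, n_months: int) -> bool:
    off = month_diff(start, month)
    return 0 <= off < n_months
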