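"""Monthly outcome series and season tables.

Admission records are collapsed into per-calendar-month sums of an outcome
(admission counts, or total LOS days) for a subgroup, and into per-season
tables under two southern-hemisphere climate conventions: the four European
seasons for temperate/colder zones, and a two-season wet/dry split for the
subtropical zone.

An admission is attributed wholly to the calendar month of its admission date,
even when the stay spans a month boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._calendar import Month, add_months, month_diff, month_of_date
from .errors import ConfigurationError, DataIntegrityError, EmptyTableError
from .synthetic_cohort import AdmissionRecord, Patient, ZONES

logger = logging.getLogger(__name__)

#: Southern-hemisphere four-season map (temperate and colder zones).
_TEMPERATE_SEASONS = {
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
    9: "spring", 10: "spring", 11: "spring",
}

#: Subtropical wet/dry split, labelled summer/winter: wet season Nov-Apr,
#: dry season May-Oct.
_SUBTROPICAL_SEASONS = {
    11: "summer", 12: "summer", 1: "summer", 2: "summer", 3: "summer", 4: "summer",
    5: "winter", 6: "winter", 7: "winter", 8: "winter", 9: "winter", 10: "winter",
}

SEASONS_BY_ZONE = {
    "temperate": ("summer", "autumn", "winter", "spring"),
    "colder": ("summer", "autumn", "winter", "spring"),
    "subtropical": ("summer", "winter"),
}


def assign_season(month: int, zone: str) -> str:
    """Season label for a calendar month under the zone's climate convention."""
    if not 1 <= month <= 12:
        raise ConfigurationError(f"month must be in 1..12, got {month}")
    if zone == "subtropical":
        return _SUBTROPICAL_SEASONS[month]
    if zone in ("temperate", "colder"):
        return _TEMPERATE_SEASONS[month]
    raise ConfigurationError(f"unknown zone {zone!r}")


@dataclass
class MonthlySeries:
    """Consecutive calendar-month sums of one outcome for one subgroup."""

    subgroup: str
    outcome: str  # "admissions" | "los"
    start: Month
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ConfigurationError("series values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    def calendar_months(self) -> List[int]:
        return [add_months(self.start, i)[1] for i in range(len(self.values))]


def monthly_series(
    records: Iterable[AdmissionRecord],
    patients: Sequence[Patient],
    outcome: str,
    window: Tuple[Month, int],
    subgroup: Optional[str] = None,
    patient_filter: Optional[Callable[[Patient], bool]] = None,
) -> MonthlySeries:
    """Sum an outcome over all passing patients within each calendar month.

    `subgroup` filters by zone (None = whole cohort); `patient_filter` is an
    arbitrary extra predicate.  Months with no admissions are 0, not gaps.
    Records outside the window are excluded with a logged count; a record
    referencing an unknown patient is a data-integrity error.
    """
    if outcome not in ("admissions", "los"):
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    start, n_months = window
    if n_months < 1:
        raise ConfigurationError("window must span at least one month")
    by_id = {p.patient_id: p for p in patients}

    values = np.zeros(n_months)
    n_excluded = 0
    for rec in records:
        pat = by_id.get(rec.patient_id)
        if pat is None:
            raise DataIntegrityError(f"record references unknown patient {rec.patient_id!r}")
        if subgroup is not None and pat.zone != subgroup:
            continue
        if patient_filter is not None and not patient_filter(pat):
            continue
        off = month_diff(start, month_of_date(rec.admit_date))
        if not 0 <= off < n_months:
            n_excluded += 1
            continue
        values[off] += 1 if outcome == "admissions" else rec.los_days
    if n_excluded:
        logger.warning("excluded %d out-of-window records", n_excluded)
    return MonthlySeries(subgroup or "all", outcome, start, values)


@dataclass
class SeasonTable:
    """Per-season admission and LOS totals with percentage shares.

    by_season: one row per (zone, season) with counts and shares of the zone
    total; by_zone: zone totals and shares of the grand total.
    """

    by_season: pd.DataFrame
    by_zone: pd.DataFrame
    grand_admissions: int
    grand_los: int


def season_table(
    records: Iterable[AdmissionRecord],
    patients: Sequence[Patient],
) -> SeasonTable:
    """Tabulate admissions and LOS by climate zone and season.

    Shares within a zone and zone shares of the grand total are reported in
    percent at full precision; report formatting applies the printed rounding.
    """
    by_id = {p.patient_id: p for p in patients}
    rows = []
    for rec in records:
        pat = by_id.get(rec.patient_id)
        if pat is None:
            raise DataIntegrityError(f"record references unknown patient {rec.patient_id!r}")
        season = assign_season(rec.admit_date.month, pat.zone)
        rows.append((pat.zone, season, rec.los_days))
    if not rows:
        raise EmptyTableError("no admission records to tabulate")

    df = pd.DataFrame(rows, columns=["zone", "season", "los"])
    by_season = (
        df.groupby(["zone", "season"])
        .agg(admissions=("los", "size"), los=("los", "sum"))
        .reset_index()
    )
    # ensure every season of each present zone appears, zero-filled
    full = []
    for zone in by_season["zone"].unique():
        for season in SEASONS_BY_ZONE[zone]:
            full.append((zone, season))
    by_season = (
        pd.DataFrame(full, columns=["zone", "season"])
        .merge(by_season, how="left", on=["zone", "season"])
        .fillna({"admissions": 0, "los": 0})
        .astype({"admissions": int, "los": int})
    )

    zone_tot = by_season.groupby("zone")[["admissions", "los"]].sum()
    grand_adm = int(zone_tot["admissions"].sum())
    grand_los = int(zone_tot["los"].sum())

    by_season = by_season.merge(
        zone_tot.rename(columns={"admissions": "zone_adm", "los": "zone_los"}),
        on="zone",
    )
    by_season["adm_share_pct"] = 100.0 * by_season["admissions"] / by_season["zone_adm"]
    by_season["los_share_pct"] = 100.0 * by_season["los"] / by_season["zone_los"]
    by_season = by_season.drop(columns=["zone_adm", "zone_los"])

    by_zone = zone_tot.reset_index()
    by_zone["adm_share_pct"] = 100.0 * by_zone["admissions"] / grand_adm
    by_zone["los_share_pct"] = 100.0 * by_zone["los"] / grand_los
    return SeasonTable(by_season, by_zone, grand_adm, grand_los)
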