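"""Shared fixtures: printed-count season fixture and profile builders."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from seasonsync import AdmissionRecord, Patient
from seasonsync.seasonal import SeasonalProfile

# Published per-zone season totals for the 136-patient cohort, 2010-2012:
# (zone, season) -> (admissions, LOS days).  Representative admission months:
# temperate/colder summer=Jan, autumn=Apr, winter=Jul, spring=Oct; subtropical
# wet(summer)=Jan, dry(winter)=Jul.
SEASON_TOTALS = {
    ("colder", "summer"): (113, 457),
    ("colder", "autumn"): (114, 645),
    ("colder", "winter"): (107, 522),
    ("colder", "spring"): (109, 554),
    ("temperate", "summer"): (21, 75),
    ("temperate", "autumn"): (21, 73),
    ("temperate", "winter"): (34, 138),
    ("temperate", "spring"): (43, 192),
    ("subtropical", "summer"): (98, 338),
    ("subtropical", "winter"): (157, 633),
}

_SEASON_MONTH = {"summer": 1, "autumn": 4, "winter": 7, "spring": 10}


def _split_integer(total: int, parts: int) -> list[int]:
    """parts integers >= 0 summing to total (as equal as possible)."""
    base, rem = divmod(total, parts)
    return [base + 1] * rem + [base] * (parts - rem)


@pytest.fixture(scope="session")
def season_fixture_cohort():
    """Synthetic cohort whose season table reproduces the published totals.

    One patient per zone; each (zone, season) cell gets its printed number of
    admissions in a representative month of that season, with integer LOS
    values splitting the printed LOS total.
    """
    patients = [
        Patient(f"{z}-1", "control", z, 72.0, "M") for z in ("subtropical", "temperate", "colder")
    ]
    records = []
    for (zone, season), (n_adm, los_total) in SEASON_TOTALS.items():
        month = _SEASON_MONTH[season]
        for los in _split_integer(los_total, n_adm):
            records.append(AdmissionRecord(f"{zone}-1", dt.date(2011, month, 15), los))
    return patients, records


def make_sinusoid_profile(amplitude: float, phase_months: float = 0.0,
                          label: str = "sinusoid") -> SeasonalProfile:
    """12-month sinusoidal seasonal profile (percent units, zero mean)."""
    months = np.arange(12)
    dev = amplitude * np.sin(2.0 * np.pi * (months - phase_months) / 12.0)
    return SeasonalProfile(label, dev, np.zeros(12), 2)


@pytest.fixture
def sinusoid_profile():
    return make_sinusoid_profile(100.0)
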