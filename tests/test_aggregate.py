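"""Monthly aggregation, season maps, and the printed-total season table."""

import datetime as dt

import numpy as np
import pytest

from seasonsync import AdmissionRecord, Patient, assign_season, monthly_series, season_table
from seasonsync.aggregate import SEASONS_BY_ZONE
from seasonsync.errors import ConfigurationError, DataIntegrityError, EmptyTableError

WINDOW = ((2010, 1), 36)
PATIENTS = [Patient("p1", "control", "temperate", 70.0, "M")]


def rec(year, month, day=10, los=1, pid="p1"):
    return AdmissionRecord(pid, dt.date(year, month, day), los)


def test_no_records_all_zero_series():
    s = monthly_series([], PATIENTS, "admissions", WINDOW)
    assert len(s) == 36
    assert (s.values == 0).all()


def test_counts_and_los_sums_in_one_month():
    records = [rec(2010, 3, los=2), rec(2010, 3, los=3), rec(2010, 3, los=5)]
    adm = monthly_series(records, PATIENTS, "admissions", WINDOW)
    los = monthly_series(records, PATIENTS, "los", WINDOW)
    assert adm.values[2] == 3 and adm.values.sum() == 3
    assert los.values[2] == 10 and los.values.sum() == 10


def test_admission_attributed_to_admit_month_even_if_stay_spans():
    records = [rec(2010, 1, day=30, los=10)]  # stay runs into February
    los = monthly_series(records, PATIENTS, "los", WINDOW)
    assert los.values[0] == 10 and los.values[1] == 0


def test_unknown_patient_is_integrity_error():
    with pytest.raises(DataIntegrityError):
        monthly_series([rec(2010, 1, pid="ghost")], PATIENTS, "admissions", WINDOW)


def test_out_of_window_records_excluded():
    records = [rec(2009, 12), rec(2010, 1), rec(2013, 1)]
    s = monthly_series(records, PATIENTS, "admissions", WINDOW)
    assert s.values.sum() == 1


def test_conservation_under_any_filter():
    """Sum of the series equals the number (or LOS total) of in-window
    records passing the filter, for random record sets."""
    rng = np.random.default_rng(12)
    patients = [
        Patient(f"p{i}", "control", z, 70.0, "F")
        for i, z in enumerate(["temperate", "colder", "subtropical"] * 4)
    ]
    records = []
    for _ in range(300):
        pid = f"p{rng.integers(0, len(patients))}"
        y, m = int(rng.integers(2010, 2013)), int(rng.integers(1, 13))
        records.append(AdmissionRecord(pid, dt.date(y, m, 5), int(rng.integers(1, 20))))
    for zone in (None, "temperate", "colder"):
        adm = monthly_series(records, patients, "admissions", WINDOW, subgroup=zone)
        los = monthly_series(records, patients, "los", WINDOW, subgroup=zone)
        by_id = {p.patient_id: p for p in patients}
        keep = [r for r in records if zone is None or by_id[r.patient_id].zone == zone]
        assert adm.values.sum() == len(keep)
        assert los.values.sum() == sum(r.los_days for r in keep)


# ---------------------------------------------------------------------------
# season assignment


@pytest.mark.parametrize(
    "month,zone,season",
    [
        (6, "temperate", "winter"),
        (12, "temperate", "summer"),
        (2, "colder", "summer"),
        (3, "temperate", "autumn"),
        (9, "colder", "spring"),
        (11, "temperate", "spring"),
        (1, "subtropical", "summer"),
        (4, "subtropical", "summer"),
        (11, "subtropical", "summer"),
        (5, "subtropical", "winter"),
        (10, "subtropical", "winter"),
    ],
)
def test_assign_season_climate_maps(month, zone, season):
    assert assign_season(month, zone) == season


def test_every_month_maps_to_exactly_one_season():
    for zone, seasons in SEASONS_BY_ZONE.items():
        for m in range(1, 13):
            assert assign_season(m, zone) in seasons


def test_assign_season_errors():
    with pytest.raises(ConfigurationError):
        assign_season(6, "tropical")
    with pytest.raises(ConfigurationError):
        assign_season(0, "temperate")


# ---------------------------------------------------------------------------
# season table


def test_season_table_empty_input():
    with pytest.raises(EmptyTableError):
        season_table([], PATIENTS)


def test_all_in_one_season_full_share():
    records = [rec(2010, 7, los=4), rec(2011, 6, los=2)]
    table = season_table(records, PATIENTS)
    by = table.by_season.set_index("season")
    assert by.loc["winter", "adm_share_pct"] == 100.0
    assert by.loc["summer", "admissions"] == 0


def test_season_table_reproduces_published_subgroup_totals(season_fixture_cohort):
    """Printed zone totals: 443/119/255 admissions, 2178/478/971 LOS days,
    grand totals 817 and 3627."""
    patients, records = season_fixture_cohort
    table = season_table(records, patients)
    zone = table.by_zone.set_index("zone")
    assert zone.loc["colder", "admissions"] == 443
    assert zone.loc["temperate", "admissions"] == 119
    assert zone.loc["subtropical", "admissions"] == 255
    assert zone.loc["colder", "los"] == 2178
    assert zone.loc["temperate", "los"] == 478
    assert zone.loc["subtropical", "los"] == 971
    assert table.grand_admissions == 817
    assert table.grand_los == 3627


def test_season_table_reproduces_published_shares(season_fixture_cohort):
    """Within-zone shares at 1 dp match the printed table, e.g. temperate
    spring admissions 36.1% and subtropical winter 61.6%."""
    patients, records = season_fixture_cohort
    by = season_table(records, patients).by_season.set_index(["zone", "season"])
    assert round(by.loc[("temperate", "spring"), "adm_share_pct"], 1) == 36.1
    assert round(by.loc[("subtropical", "winter"), "adm_share_pct"], 1) == 61.6
    assert round(by.loc[("colder", "summer"), "adm_share_pct"], 1) == 25.5
    assert round(by.loc[("temperate", "spring"), "los_share_pct"], 1) == 40.2
    # shares within each zone sum to 100
    sums = season_table(records, patients).by_season.groupby("zone")["adm_share_pct"].sum()
    assert np.allclose(sums, 100.0)
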