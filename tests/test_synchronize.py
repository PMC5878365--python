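"""Synchronized profile: rotations, pooling, dropout, and brute-force oracle."""

import numpy as np
import pytest

from seasonsync import ScheduleEntry, max_sync_deviation, synchronized_profile
from seasonsync.errors import ConfigurationError, EmptyProfileError
from seasonsync.seasonal import SeasonalProfile
from seasonsync.synchronize import SynchronizedProfile

from conftest import make_sinusoid_profile


def profile(mean_dev, label="z"):
    return SeasonalProfile(label, np.asarray(mean_dev, float), np.zeros(12), 3)


def brute_force_profile(profiles, schedule):
    """Independent double loop over (patient, month)."""
    sync = np.full(12, np.nan)
    n_at = np.zeros(12, dtype=int)
    for i in range(1, 13):
        total, n = 0.0, 0
        for e in schedule:
            if e.months_monitored >= i:
                cal = (e.commencement_month + i - 2) % 12 + 1
                total += profiles[e.zone].mean_dev[cal - 1]
                n += 1
        n_at[i - 1] = n
        if n:
            sync[i - 1] = total / n
    return sync, n_at


def test_single_january_patient_identity_rotation():
    p = profile(np.arange(12, dtype=float) * 3 - 10)
    sp = synchronized_profile({"z": p}, [ScheduleEntry("z", 1, 12)])
    np.testing.assert_allclose(sp.sync_dev, p.mean_dev, atol=1e-12)
    assert (sp.n_at_month == 1).all()


def test_antiphase_commencements_cancel_sinusoid():
    p = make_sinusoid_profile(80.0, label="z")
    schedule = [ScheduleEntry("z", 2, 12), ScheduleEntry("z", 8, 12)]
    sp = synchronized_profile({"z": p}, schedule)
    np.testing.assert_allclose(sp.sync_dev, 0.0, atol=1e-12)


def test_matches_brute_force_on_random_schedules():
    rng = np.random.default_rng(31)
    profiles = {
        "a": profile(rng.normal(0, 50, 12), "a"),
        "b": profile(rng.normal(0, 50, 12), "b"),
        "c": profile(rng.normal(0, 50, 12), "c"),
    }
    for _ in range(25):
        n = int(rng.integers(1, 11))
        schedule = [
            ScheduleEntry(
                zone=rng.choice(["a", "b", "c"]),
                commencement_month=int(rng.integers(1, 13)),
                months_monitored=int(rng.integers(1, 13)),
            )
            for _ in range(n)
        ]
        sp = synchronized_profile(profiles, schedule)
        sync, n_at = brute_force_profile(profiles, schedule)
        np.testing.assert_array_equal(sp.n_at_month, n_at)
        np.testing.assert_allclose(sp.sync_dev, sync, atol=1e-12, equal_nan=True)


def test_dropout_shrinks_denominator():
    p = profile(np.full(12, 10.0))
    schedule = [ScheduleEntry("z", 1, 12), ScheduleEntry("z", 1, 5)]
    sp = synchronized_profile({"z": p}, schedule)
    assert list(sp.n_at_month[:5]) == [2] * 5
    assert list(sp.n_at_month[5:]) == [1] * 7
    # n_at_month is non-increasing
    assert (np.diff(sp.n_at_month) <= 0).all()


def test_short_follow_up_leaves_late_months_undefined():
    p = profile(np.full(12, 4.0))
    sp = synchronized_profile({"z": p}, [ScheduleEntry("z", 3, 4)])
    assert np.isfinite(sp.sync_dev[:4]).all()
    assert np.isnan(sp.sync_dev[4:]).all()
    assert (sp.n_at_month[4:] == 0).all()


def test_missing_zone_profile_rejected():
    with pytest.raises(ConfigurationError):
        synchronized_profile({"z": profile(np.zeros(12))}, [ScheduleEntry("y", 1, 12)])


def test_single_zone_profile_bounds_sync_values():
    """Each synchronized value is a convex combination of profile values."""
    rng = np.random.default_rng(5)
    p = profile(rng.normal(0, 60, 12))
    schedule = [
        ScheduleEntry("z", int(rng.integers(1, 13)), int(rng.integers(1, 13)))
        for _ in range(40)
    ]
    sp = synchronized_profile({"z": p}, schedule)
    lo, hi = p.mean_dev.min(), p.mean_dev.max()
    defined = sp.sync_dev[sp.n_at_month > 0]
    assert ((defined >= lo - 1e-12) & (defined <= hi + 1e-12)).all()


# ---------------------------------------------------------------------------
# peak of the synchronized profile


def test_zero_profile_zero_peak():
    sp = synchronized_profile({"z": profile(np.zeros(12))}, [ScheduleEntry("z", 1, 12)])
    assert max_sync_deviation(sp)[0] == 0.0


def test_single_defined_month_negative_value():
    sp = SynchronizedProfile(
        np.array([np.nan] * 11 + [-7.0]),
        np.array([0] * 11 + [3]),
        [np.array([])] * 11 + [np.array([-6.0, -7.0, -8.0])],
    )
    peak, sd = max_sync_deviation(sp)
    assert peak == 7.0
    assert sd == pytest.approx(1.0)


def test_empty_schedule_peak_is_error():
    sp = synchronized_profile({"z": profile(np.zeros(12))}, [])
    with pytest.raises(EmptyProfileError):
        max_sync_deviation(sp)


def test_peak_matches_exhaustive_scan():
    rng = np.random.default_rng(77)
    for _ in range(10):
        p = profile(rng.normal(0, 40, 12))
        schedule = [
            ScheduleEntry("z", int(rng.integers(1, 13)), int(rng.integers(1, 13)))
            for _ in range(6)
        ]
        sp = synchronized_profile({"z": p}, schedule)
        peak, _ = max_sync_deviation(sp)
        expected = np.nanmax(np.abs(sp.sync_dev))
        assert peak == pytest.approx(expected, abs=1e-15)


def test_uniform_commencements_attenuate_sinusoid():
    """Spreading commencements evenly over 12 months drives the synchronized
    peak of a sinusoidal profile toward zero, while a point-mass schedule
    preserves the full amplitude."""
    p = make_sinusoid_profile(100.0, label="z")
    even = [ScheduleEntry("z", m, 12) for m in range(1, 13) for _ in range(5)]
    sp_even = synchronized_profile({"z": p}, even)
    np.testing.assert_allclose(sp_even.sync_dev, 0.0, atol=1e-12)
    point = [ScheduleEntry("z", 4, 12) for _ in range(60)]
    peak, _ = max_sync_deviation(synchronized_profile({"z": p}, point))
    assert peak == pytest.approx(100.0, abs=1e-9)
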