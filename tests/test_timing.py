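"""ISO-8601 rendering, timestamp reconstruction, and day splitting."""

import datetime as dt
from zoneinfo import ZoneInfo

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearstd.schema import validate
from wearstd.synthetic import FixtureSpec, generate_recording
from wearstd.timing import (
    TimingError,
    ZoneError,
    format_start_datetime,
    parse_start_datetime,
    reconstruct_timestamps,
    split_days,
)

ZONES = [
    "UTC",
    "Europe/London",
    "Europe/Berlin",
    "Europe/Lisbon",
    "Atlantic/Azores",
    "Asia/Jerusalem",
    "America/New_York",
    "America/Los_Angeles",
    "America/Sao_Paulo",
    "Australia/Sydney",
    "Australia/Adelaide",
    "Asia/Kolkata",
    "Asia/Kathmandu",
    "Asia/Tokyo",
    "Pacific/Auckland",
    "Pacific/Chatham",
    "Africa/Nairobi",
    "America/St_Johns",
    "Atlantic/Reykjavik",
    "Europe/Moscow",
]


def test_epoch_renders_with_z_in_zero_offset_zone():
    assert format_start_datetime(0.0, "UTC") == "1970-01-01T00:00:00.000Z"


def test_epoch_renders_with_numeric_offset_in_berlin():
    assert format_start_datetime(0.0, "Europe/Berlin") == "1970-01-01T01:00:00.000+01:00"


def test_millisecond_rendering_at_end_of_day():
    assert format_start_datetime(86399.5, "UTC") == "1970-01-01T23:59:59.500Z"


def test_unknown_zone_raises():
    with pytest.raises(ZoneError):
        format_start_datetime(0.0, "Mars/Olympus")


def test_reconstruct_from_epoch():
    np.testing.assert_allclose(
        reconstruct_timestamps("1970-01-01T00:00:00.000Z", 100.0, 3),
        [0.0, 0.01, 0.02],
    )


def test_reconstruct_honors_utc_offset():
    np.testing.assert_allclose(
        reconstruct_timestamps("1970-01-01T01:00:00.000+01:00", 1.0, 2), [0.0, 1.0]
    )


def test_reconstruction_matches_stored_timestamps():
    spec = FixtureSpec(seed=31, duration=30.0, systems=())
    rec, _ = generate_recording(
        spec, np.random.default_rng(31), parse_start_datetime(spec.start_date_time)
    )
    loc = rec.sensor_units["SU"].locations["LowerBack"]
    rebuilt = reconstruct_timestamps(
        loc.timing.start_date_time, loc.fs["Acc"], loc.acc.shape[0]
    )
    assert np.max(np.abs(rebuilt - loc.timing.timestamp)) < 0.5 / loc.fs["Acc"]


@settings(max_examples=300, deadline=None)
@given(
    st.integers(min_value=0, max_value=2051222400_000),  # 1970..2035, in ms
    st.sampled_from(ZONES),
)
def test_format_and_parse_are_mutual_inverses(ms, zone):
    ts = ms / 1000.0
    rendered = format_start_datetime(ts, zone)
    assert parse_start_datetime(rendered) == pytest.approx(ts, abs=5e-4)
    # and the 'Z' rule fires iff the UTC offset at that instant is zero
    offset = dt.datetime.fromtimestamp(ts, tz=ZoneInfo(zone)).utcoffset()
    assert rendered.endswith("Z") == (offset == dt.timedelta(0))


def test_z_rule_tracks_dst_in_zones_crossing_zero_offset():
    # Lisbon: +00:00 in winter (Z), +01:00 in summer (numeric offset)
    winter = parse_start_datetime("2023-01-15T12:00:00.000+00:00")
    summer = parse_start_datetime("2023-07-15T12:00:00.000+01:00")
    assert format_start_datetime(winter, "Europe/Lisbon").endswith("Z")
    assert format_start_datetime(summer, "Europe/Lisbon").endswith("+01:00")


def _lower_back(rec):
    return rec.sensor_units["SU"].locations["LowerBack"]


def _make_rec(seed, start, hours, fs=None):
    kwargs = {}
    if fs is not None:
        kwargs["fs"] = fs
    spec = FixtureSpec(
        seed=seed, start_date_time=start, duration=hours * 3600.0, systems=(), **kwargs
    )
    return generate_recording(
        spec, np.random.default_rng(seed), parse_start_datetime(spec.start_date_time)
    )[0]


def test_midnight_crossing_recording_splits_in_two():
    rec = _make_rec(41, "2023-05-15T22:00:00.000+02:00", 4)
    segs = split_days(rec)
    assert [s.local_date.isoformat() for s in segs] == ["2023-05-15", "2023-05-16"]
    counts = [_lower_back(s.recording).acc.shape[0] for s in segs]
    assert counts == [720000, 720000]  # 2 h each at 100 Hz
    assert segs[1].recording.sensor_units["SU"].locations[
        "LowerBack"
    ].timing.start_date_time == "2023-05-16T00:00:00.000+02:00"


def test_single_day_recording_is_one_identical_segment():
    rec = _make_rec(42, "2023-05-15T09:00:00.000+02:00", 2)
    segs = split_days(rec)
    assert len(segs) == 1
    np.testing.assert_array_equal(
        _lower_back(segs[0].recording).acc, _lower_back(rec).acc
    )


def test_spring_forward_day_has_23_wall_clock_hours():
    # Berlin 2023-03-26: 02:00->03:00 skipped; recording 23:00 (25th) -> 06:00 local
    rec = _make_rec(43, "2023-03-25T23:00:00.000+01:00", 6)
    segs = split_days(rec)
    assert len(segs) == 2
    # 6 h of UTC elapsed: 1 h before midnight, 5 h (= 6 wall-clock hours) after
    assert _lower_back(segs[0].recording).acc.shape[0] == 360000
    assert _lower_back(segs[1].recording).acc.shape[0] == 1800000


def test_fall_back_day_has_25_wall_clock_hours():
    # Berlin 2023-10-29: 03:00->02:00; midnight-to-midnight covers 25 h of UTC
    rec = _make_rec(44, "2023-10-28T23:30:00.000+02:00", 27)
    segs = split_days(rec)
    assert [s.local_date.isoformat() for s in segs] == [
        "2023-10-28", "2023-10-29", "2023-10-30",
    ]
    assert _lower_back(segs[1].recording).acc.shape[0] == 25 * 3600 * 100


def test_segments_partition_every_sensor_exactly():
    fs = {"Acc": 100.0, "Gyr": 100.0, "Mag": 50.0, "Bar": 25.0, "Temp": 1.0}
    rec = _make_rec(45, "2023-05-15T21:17:00.000+02:00", 30, fs=fs)
    segs = split_days(rec)
    orig = _lower_back(rec)
    for attr in ("acc", "gyr", "mag", "bar", "temp"):
        parts = [getattr(_lower_back(s.recording), attr) for s in segs]
        np.testing.assert_array_equal(np.concatenate(parts), getattr(orig, attr))
    assert all(0 < s.duration <= 90000 for s in segs)


def test_exact_midnight_sample_opens_the_new_day():
    rec = _make_rec(46, "2023-05-15T23:59:59.000+02:00", 1.0 / 1800)  # 2 s, 200 samples
    segs = split_days(rec)
    assert len(segs) == 2
    first = _lower_back(segs[1].recording)
    # the 00:00:00.000 sample belongs to day 2
    assert first.timing.start_date_time == "2023-05-16T00:00:00.000+02:00"
    assert _lower_back(segs[0].recording).acc.shape[0] == 100


def test_split_days_requires_locations():
    from wearstd.schema import Recording

    with pytest.raises(TimingError):
        split_days(Recording())


def test_day_segments_revalidate_as_seven_day_dataset():
    from wearstd.schema import SubjectDataset, TimeMeasurement, Type2Recording

    rec = _make_rec(47, "2023-05-15T20:00:00.000+02:00", 10)
    days = [Type2Recording(s.recording) for s in split_days(rec)]
    ds = SubjectDataset("1001", {"T1": TimeMeasurement(seven_day=days)})
    assert validate(ds, strict=True) == []
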