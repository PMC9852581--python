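"""Timing references: Unix timestamps, IANA zones, ISO-8601 start times,
timestamp reconstruction, and midnight-to-midnight day splitting.

All stored timestamps are Unix seconds (UTC, leap seconds ignored); local
wall-clock rendering happens only at the ``StartDateTime`` boundary, through
the recording's IANA ``TimeZone``.  Ambiguous local times during fall-back are
never a problem because the authoritative instant is always the UTC timestamp;
the rendered offset is simply the one in force at that instant.

Day splitting cuts a continuous multi-day recording at local midnights into
``Day1..DayN`` segments.  Intervals are half-open ``[midnight, next midnight)``:
a sample falling exactly on midnight opens the new day.  Daylight-saving
transitions make individual days 23 or 25 wall-clock hours long; sample counts
follow elapsed UTC time, not wall-clock time.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from zoneinfo import ZoneInfo, ZoneInfoNotFoundError

import numpy as np

from .schema import LocationData, Recording, SensorUnit, TimingInfo

__all__ = [
    "DaySegment",
    "ZoneError",
    "TimingError",
    "check_zone",
    "format_start_datetime",
    "parse_start_datetime",
    "reconstruct_timestamps",
    "split_days",
    "recording_local_dates",
]


class ZoneError(ValueError):
    """Not a valid IANA time-zone identifier."""


class TimingError(ValueError):
    """Recording lacks the timing information an operation needs."""


def check_zone(zone: str) -> ZoneInfo:
    try:
        return ZoneInfo(zone)
    except (ZoneInfoNotFoundError, ValueError, TypeError):
        raise ZoneError(f"unknown IANA time zone {zone!r}") from None


def format_start_datetime(unix_ts: float, zone: str) -> str:
    """Render a Unix timestamp as local ISO-8601 with millisecond precision.

    Format is 'YYYY-MM-DDThh:mm:ss.SSS±hh:mm'; when the UTC offset at that
    instant is exactly zero the offset is replaced with 'Z'.
    """
    tz = check_zone(zone)
    # round to the millisecond first so 23:59:59.9996 does not render as .000
    # with an unrounded date
    ms_total = round(float(unix_ts) * 1000.0)
    dt = _dt.datetime.fromtimestamp(ms_total / 1000.0, tz=tz)
    ms = round(ms_total - int(ms_total // 1000) * 1000)
    body = dt.strftime("%Y-%m-%dT%H:%M:%S") + f".{ms:03d}"
    offset = dt.utcoffset()
    assert offset is not None
    if offset == _dt.timedelta(0):
        return body + "Z"
    total_min = int(offset.total_seconds() // 60)
    sign = "+" if total_min >= 0 else "-"
    total_min = abs(total_min)
    return body + f"{sign}{total_min // 60:02d}:{total_min % 60:02d}"


def parse_start_datetime(value: str) -> float:
    """Inverse of :func:`format_start_datetime`: ISO-8601 string -> Unix seconds."""
    try:
        dt = _dt.datetime.fromisoformat(value)
    except ValueError as exc:
        raise ValueError(f"unparseable ISO-8601 start time {value!r}: {exc}") from None
    if dt.tzinfo is None:
        raise ValueError(
            f"start time {value!r} carries no UTC offset; an offset or 'Z' is required"
        )
    return dt.timestamp()


def reconstruct_timestamps(start_date_time: str, fs: float, n: int) -> np.ndarray:
    """Recreate the per-sample Unix timestamp vector from start time and rate.

    ``t[k] = unix(start) + k / fs`` for ``k = 0..n-1``.
    """
    if fs <= 0:
        raise ValueError(f"sampling frequency must be > 0, got {fs}")
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    t0 = parse_start_datetime(start_date_time)
    return t0 + np.arange(n, dtype=float) / float(fs)


@dataclass
class DaySegment:
    """One midnight-to-midnight slice of a multi-day recording."""

    day_index: int  # 1-based
    local_date: _dt.date
    recording: Recording
    duration: float  # seconds of signal covered, > 0 and <= 25 h


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _acc_times(loc: LocationData) -> np.ndarray:
    """Per-sample Unix times of the Acc-rate signals of one location."""
    ti = loc.timing
    n = np.asarray(loc.acc).shape[0]
    if ti.timestamp is not None and np.asarray(ti.timestamp).shape[0] == n:
        return np.asarray(ti.timestamp, dtype=float)
    if "Acc" not in loc.fs:
        raise TimingError("no Timestamp vector and no Acc sampling frequency")
    return reconstruct_timestamps(ti.start_date_time, loc.fs["Acc"], n)


def _signal_times(loc: LocationData, attr: str, n: int) -> np.ndarray:
    """Unix times of signal *attr*, using its own rate and start reference."""
    from .schema import SIGNAL_FIELDS

    name = SIGNAL_FIELDS[attr]
    ti = loc.timing
    if attr in ("acc", "gyr", "mag", "quat") and ti.timestamp is not None:
        ts = np.asarray(ti.timestamp, dtype=float)
        if ts.shape[0] == n:
            return ts
    if attr == "temp" and ti.start_date_time_temp is not None:
        start = ti.start_date_time_temp
    else:
        start = ti.start_date_time
    fs = loc.fs.get(name)
    if fs is None:
        raise TimingError(f"no sampling frequency for signal {name}")
    return reconstruct_timestamps(start, fs, n)


def recording_local_dates(rec: Recording) -> tuple[_dt.date, _dt.date] | None:
    """(first, last) local calendar date spanned by the Acc signal, or None."""
    for unit in rec.sensor_units.values():
        for loc in unit.locations.values():
            try:
                tz = check_zone(loc.timing.time_zone)
                times = _acc_times(loc)
            except (ZoneError, TimingError, ValueError):
                return None
            first = _dt.datetime.fromtimestamp(times[0], tz=tz).date()
            last = _dt.datetime.fromtimestamp(times[-1], tz=tz).date()
            return first, last
    return None


def _local_midnight(date: _dt.date, tz: ZoneInfo) -> float:
    """Unix time of local midnight opening *date* (fold=0 under DST skips)."""
    return _dt.datetime(date.year, date.month, date.day, tzinfo=tz).timestamp()


def split_days(rec: Recording, zone: str | None = None) -> list[DaySegment]:
    """Split a continuous recording at local midnights into day segments.

    Every signal of every location is cut at its own sample index nearest the
    midnight boundary (computed from its own timestamps or rate), so the
    segments partition each signal exactly: concatenating them reproduces the
    original arrays sample-for-sample.  Boundaries are half-open — a sample
    landing exactly on midnight belongs to the new day.
    """
    locs = [
        (unit_key, loc_name, loc)
        for unit_key, unit in rec.sensor_units.items()
        for loc_name, loc in unit.locations.items()
    ]
    if not locs:
        raise TimingError("recording has no sensor locations to split")
    zone = zone or locs[0][2].timing.time_zone
    tz = check_zone(zone)

    # overall span from the Acc timelines
    t_first = min(_acc_times(loc)[0] for _, _, loc in locs)
    t_last = max(_acc_times(loc)[-1] for _, _, loc in locs)
    d0 = _dt.datetime.fromtimestamp(t_first, tz=tz).date()
    d1 = _dt.datetime.fromtimestamp(t_last, tz=tz).date()
    n_days = (d1 - d0).days + 1
    # Unix times of the n_days+1 midnights bracketing the recording
    midnights = [
        _local_midnight(d0 + _dt.timedelta(days=k), tz) for k in range(n_days + 1)
    ]

    segments: list[DaySegment] = []
    day_index = 0
    for k in range(n_days):
        lo, hi = midnights[k], midnights[k + 1]
        day_units: dict[str, SensorUnit] = {}
        any_samples = False
        seg_first, seg_last = np.inf, -np.inf
        for unit_key, loc_name, loc in locs:
            sliced, t_lo, t_hi = _slice_location(loc, lo, hi)
            if sliced is None:
                continue
            any_samples = True
            seg_first = min(seg_first, t_lo)
            seg_last = max(seg_last, t_hi)
            day_units.setdefault(unit_key, SensorUnit()).locations[loc_name] = sliced
        if not any_samples:
            continue
        day_index += 1
        segments.append(
            DaySegment(
                day_index=day_index,
                local_date=d0 + _dt.timedelta(days=k),
                recording=Recording(sensor_units=day_units, standards=None),
                duration=float(seg_last - seg_first),
            )
        )
    return segments


def _slice_location(
    loc: LocationData, lo: float, hi: float
) -> tuple[LocationData | None, float, float]:
    """Slice every signal of *loc* to samples with time in [lo, hi).

    Returns (sliced location, first sample time, last sample time + one Acc
    period); (None, -, -) when no Acc sample falls in the window.
    """
    acc_t = _acc_times(loc)
    i0, i1 = np.searchsorted(acc_t, [lo, hi], side="left")
    if i1 <= i0:
        return None, 0.0, 0.0
    ti = loc.timing
    tz = ti.time_zone
    new_arrays: dict[str, np.ndarray | None] = {}
    temp_start: str | None = None
    for attr, arr in loc.signals():
        n = np.asarray(arr).shape[0]
        t = _signal_times(loc, attr, n)
        j0, j1 = np.searchsorted(t, [lo, hi], side="left")
        new_arrays[attr] = np.asarray(arr)[j0:j1]
        if attr == "temp" and j1 > j0:
            temp_start = format_start_datetime(float(t[j0]), tz)
    new_ts = None
    if ti.timestamp is not None and np.asarray(ti.timestamp).shape[0] == acc_t.shape[0]:
        new_ts = np.asarray(ti.timestamp, dtype=float)[i0:i1]
    new_timing = TimingInfo(
        start_date_time=format_start_datetime(float(acc_t[i0]), tz),
        time_zone=tz,
        timestamp=new_ts,
        start_date_time_temp=temp_start,
    )
    sliced = LocationData(
        acc=new_arrays.get("acc"),
        timing=new_timing,
        fs=dict(loc.fs),
        gyr=new_arrays.get("gyr"),
        mag=new_arrays.get("mag"),
        bar=new_arrays.get("bar"),
        temp=new_arrays.get("temp"),
        quat=new_arrays.get("quat"),
    )
    fs_acc = loc.fs.get("Acc")
    period = 1.0 / fs_acc if fs_acc else 0.0
    return sliced, float(acc_t[i0]), float(acc_t[i1 - 1]) + period
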