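"""In-memory data model for standardized wearable-movement datasets.

One subject is a folder tree of *time measurements* (T1..Tn), each holding up
to three recording contexts: a structured ``Laboratory`` session (tests with
repeated trials), an unscripted ``Free-living`` session, and a multi-day
real-world recording split ``Day1..DayN``.  Every recording is a set of sensor
units — the main wearable under the key ``SU``, any further device type under
``SU_<DeviceName>`` — carrying per-location signal matrices in standardized
axes and units, timing references, and optionally a ``Standards`` block with
gold-standard walking sequences (see :mod:`wearstd.goldstd`).

Validation is a separate pass that never aborts reading: malformed legacy data
can always be loaded and inspected; :func:`validate` returns the list of rule
violations as data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

from .conventions import LocationRegistry

__all__ = [
    "SubjectDataset",
    "TimeMeasurement",
    "Type1Recording",
    "Type2Recording",
    "Recording",
    "SensorUnit",
    "LocationData",
    "TimingInfo",
    "InfoForAlgo",
    "Violation",
    "make_subject_id",
    "validate",
    "SIGNAL_FIELDS",
    "TRIAXIAL_FIELDS",
]

#: MATLAB-side field name for each signal attribute, in canonical order.
SIGNAL_FIELDS = {
    "acc": "Acc",
    "gyr": "Gyr",
    "mag": "Mag",
    "bar": "Bar",
    "temp": "Temp",
    "quat": "Quat",
}
TRIAXIAL_FIELDS = ("acc", "gyr", "mag")

_SUBJECT_ID_RE = re.compile(r"^[1-9]\d{3}$")
_ISO_RE = re.compile(
    r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}\.\d{3}(Z|[+-]\d{2}:\d{2})$"
)


def make_subject_id(site: int, participant: int) -> str:
    """Compose a consortium-style four-digit subject ID ``snnn``.

    The first digit is the clinical site, the remaining three the zero-padded
    participant number within that site; e.g. site 1, participant 1 -> "1001".
    """
    if not 1 <= site <= 9:
        raise ValueError(f"site must be in 1..9, got {site}")
    if not 1 <= participant <= 999:
        raise ValueError(f"participant must be in 1..999, got {participant}")
    return f"{site}{participant:03d}"


@dataclass
class TimingInfo:
    """The four timing references of a recording location.

    ``start_date_time`` is local wall-clock time in ISO-8601 with millisecond
    precision and a numeric UTC offset ('Z' when the offset is zero);
    ``time_zone`` an IANA name; ``timestamp`` optional per-sample Unix seconds;
    ``start_date_time_temp`` the start of the temperature sensor's own,
    typically slower, timeline.
    """

    start_date_time: str
    time_zone: str
    timestamp: np.ndarray | None = None
    start_date_time_temp: str | None = None


@dataclass
class InfoForAlgo:
    """Metadata required by processing algorithms (anthropometrics, device)."""

    sensor_type: str | None = None
    attachment: str | None = None  # "body-worn" | "body-attached"
    anthropometrics: dict[str, float] = field(default_factory=dict)
    walking_aid: bool | None = None
    extras: dict[str, Any] = field(default_factory=dict)


@dataclass
class LocationData:
    """Signals of one sensor unit at one body location.

    Tri-axial matrices are N x 3 with columns ordered V, ML, AP; units are
    g, deg/s, µT, hPa, °C for acc/gyr/mag/bar/temp.  ``fs`` maps each present
    signal name ("Acc", ...) to its sampling frequency in Hz.
    """

    acc: np.ndarray
    timing: TimingInfo
    fs: dict[str, float]
    gyr: np.ndarray | None = None
    mag: np.ndarray | None = None
    bar: np.ndarray | None = None
    temp: np.ndarray | None = None
    quat: np.ndarray | None = None

    def signals(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (attribute name, array) for every present signal."""
        for attr in SIGNAL_FIELDS:
            arr = getattr(self, attr)
            if arr is not None:
                yield attr, arr


@dataclass
class SensorUnit:
    """One device type; multiple same-type devices live here as locations."""

    locations: dict[str, LocationData] = field(default_factory=dict)


@dataclass
class Recording:
    """One recorded experiment: sensor units plus optional gold standards.

    ``sensor_units`` keys are ``"SU"`` for the main device and
    ``"SU_<DeviceName>"`` for others.  ``standards`` holds the processed
    gold-standard outputs (:class:`wearstd.goldstd.Standards`).
    """

    sensor_units: dict[str, SensorUnit] = field(default_factory=dict)
    standards: Any | None = None  # wearstd.goldstd.Standards


@dataclass
class Type1Recording:
    """Structured laboratory protocol: ordered tests, each with ordered trials.

    Keys are ordinal ("Test1"/"Recording1"); an optional human-readable name
    per node survives round-tripping via the ``names`` map.
    """

    tests: dict[str, dict[str, Recording]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)


@dataclass
class Type2Recording:
    """Single continuous unstructured recording (free-living / daily life)."""

    recording: Recording


@dataclass
class TimeMeasurement:
    """One evaluation time point (baseline, follow-up, ...)."""

    laboratory: Type1Recording | None = None
    free_living: Type2Recording | None = None
    seven_day: list[Type2Recording] | None = None  # Day1..DayN, consecutive days
    contextual_present: bool = False  # opaque payload, never parsed


@dataclass
class SubjectDataset:
    """Everything stored for one subject."""

    subject_id: str
    time_measurements: dict[str, TimeMeasurement] = field(default_factory=dict)
    info_for_algo: InfoForAlgo | None = None
    dataset_info: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One broken invariant: where, which rule, and a human-readable message."""

    path: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: [{self.rule}] {self.message}"


def _check_location(
    loc: LocationData, path: str, out: list[Violation]
) -> None:
    for attr in TRIAXIAL_FIELDS:
        arr = getattr(loc, attr)
        if arr is None:
            continue
        arr = np.asarray(arr)
        if arr.ndim != 2 or arr.shape[1] != 3:
            out.append(
                Violation(
                    f"{path}.{SIGNAL_FIELDS[attr]}",
                    f"{attr}-3-columns",
                    f"tri-axial signal must be N x 3 (V, ML, AP); got shape {arr.shape}",
                )
            )
    if loc.quat is not None:
        q = np.asarray(loc.quat)
        if q.ndim != 2 or q.shape[1] != 4:
            out.append(
                Violation(
                    f"{path}.Quat", "quat-4-columns",
                    f"quaternion signal must be N x 4; got shape {q.shape}",
                )
            )
    for attr, arr in loc.signals():
        name = SIGNAL_FIELDS[attr]
        if name not in loc.fs:
            out.append(
                Violation(
                    f"{path}.Fs", "fs-missing",
                    f"no sampling frequency recorded for present signal {name}",
                )
            )
        elif not loc.fs[name] > 0:
            out.append(
                Violation(
                    f"{path}.Fs.{name}", "fs-positive",
                    f"sampling frequency must be > 0, got {loc.fs[name]}",
                )
            )
    _check_timing(loc, path, out)


def _check_timing(loc: LocationData, path: str, out: list[Violation]) -> None:
    from . import timing as _timing  # deferred: timing imports this module

    ti = loc.timing
    for label, value in (
        ("StartDateTime", ti.start_date_time),
        ("StartDateTime_Temp", ti.start_date_time_temp),
    ):
        if value is None:
            continue
        if not _ISO_RE.match(value):
            out.append(
                Violation(
                    f"{path}.{label}", "iso8601-format",
                    "expected 'YYYY-MM-DDThh:mm:ss.SSS+/-hh:mm' "
                    f"(or trailing 'Z' at zero offset), got {value!r}",
                )
            )
    try:
        _timing.check_zone(ti.time_zone)
    except _timing.ZoneError as exc:
        out.append(Violation(f"{path}.TimeZone", "iana-zone", str(exc)))
        return
    if ti.timestamp is not None:
        ts = np.asarray(ti.timestamp, dtype=float)
        n_acc = np.asarray(loc.acc).shape[0] if loc.acc is not None else None
        if n_acc is not None and ts.shape[0] != n_acc:
            out.append(
                Violation(
                    f"{path}.Timestamp", "timestamp-length",
                    f"Timestamp has {ts.shape[0]} samples but Acc has {n_acc} rows",
                )
            )
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            out.append(
                Violation(
                    f"{path}.Timestamp", "timestamp-increasing",
                    "Timestamp vector must be strictly increasing",
                )
            )
        if ts.size and _ISO_RE.match(ti.start_date_time):
            expected = _timing.format_start_datetime(float(ts[0]), ti.time_zone)
            if expected != ti.start_date_time:
                out.append(
                    Violation(
                        f"{path}.StartDateTime", "startdatetime-consistency",
                        f"first timestamp renders as {expected!r} in zone "
                        f"{ti.time_zone!r}, but StartDateTime is "
                        f"{ti.start_date_time!r}",
                    )
                )


def _check_recording(
    rec: Recording,
    path: str,
    registry: LocationRegistry,
    strict: bool,
    out: list[Violation],
) -> None:
    if not rec.sensor_units:
        out.append(
            Violation(path, "sensor-unit-present", "recording has no sensor units")
        )
    for key, unit in rec.sensor_units.items():
        if key != "SU" and not re.match(r"^SU_[^_\s]+$", key):
            out.append(
                Violation(
                    f"{path}.{key}", "su-key-format",
                    "sensor-unit keys must be 'SU' or 'SU_<DeviceName>' with a "
                    "single underscore",
                )
            )
        for loc_name, loc in unit.locations.items():
            loc_path = f"{path}.{key}.{loc_name}"
            if strict and loc_name not in registry:
                out.append(
                    Violation(
                        loc_path, "location-registry",
                        f"unknown location {loc_name!r}; register it or use "
                        "non-strict (pre-existing dataset) mode",
                    )
                )
            _check_location(loc, loc_path, out)
    if rec.standards is not None:
        from . import goldstd as _goldstd

        _goldstd.check_standards(rec.standards, f"{path}.Standards", out)


def validate(dataset: SubjectDataset, strict: bool = True) -> list[Violation]:
    """Check every structural invariant; return violations as data.

    ``strict=False`` (pre-existing-dataset mode) relaxes exactly two rules:
    the four-digit ``snnn`` subject-ID pattern and the location registry —
    original project IDs and extra locations are then accepted unchanged.
    """
    out: list[Violation] = []
    registry = LocationRegistry()
    sid = dataset.subject_id
    if strict and not _SUBJECT_ID_RE.match(sid):
        out.append(
            Violation(
                sid or "<subject>", "subject-id-snnn",
                f"subject ID {sid!r} does not match the four-digit 'snnn' pattern "
                "(site digit + 3-digit participant)",
            )
        )
    expected_labels = [f"T{i}" for i in range(1, len(dataset.time_measurements) + 1)]
    if list(dataset.time_measurements) != expected_labels:
        out.append(
            Violation(
                sid, "time-measurement-labels",
                f"time-measurement labels must be {expected_labels}, got "
                f"{list(dataset.time_measurements)}",
            )
        )
    for label, tm in dataset.time_measurements.items():
        base = f"{sid}/{label}"
        if tm.laboratory is not None:
            t1 = tm.laboratory
            for test_key, trials in t1.tests.items():
                if not test_key:
                    out.append(
                        Violation(
                            f"{base}/Laboratory", "test-name-nonempty",
                            "test keys must be non-empty",
                        )
                    )
                if not trials:
                    out.append(
                        Violation(
                            f"{base}/Laboratory/{test_key}", "trial-present",
                            "each test must hold at least one trial",
                        )
                    )
                for trial_key, rec in trials.items():
                    _check_recording(
                        rec,
                        f"{base}/Laboratory/{test_key}/{trial_key}",
                        registry,
                        strict,
                        out,
                    )
        if tm.free_living is not None:
            _check_recording(
                tm.free_living.recording, f"{base}/Free-living", registry, strict, out
            )
        if tm.seven_day is not None:
            _check_seven_day(tm.seven_day, base, registry, strict, out)
    if dataset.info_for_algo is not None:
        att = dataset.info_for_algo.attachment
        if att is not None and att not in ("body-worn", "body-attached"):
            out.append(
                Violation(
                    f"{sid}/infoForAlgo.Attachment", "attachment-enum",
                    f"attachment must be 'body-worn' or 'body-attached', got {att!r}",
                )
            )
    return out


def _check_seven_day(
    days: list[Type2Recording],
    base: str,
    registry: LocationRegistry,
    strict: bool,
    out: list[Violation],
) -> None:
    from . import timing as _timing

    dates = []
    for i, day in enumerate(days, start=1):
        path = f"{base}/7-day/Day{i}"
        _check_recording(day.recording, path, registry, strict, out)
        ti = _first_timing(day.recording)
        if ti is None or not _ISO_RE.match(ti.start_date_time):
            continue
        try:
            _timing.check_zone(ti.time_zone)
        except _timing.ZoneError:
            continue
        span = _timing.recording_local_dates(day.recording)
        if span is None:
            continue
        first, last = span
        if first != last:
            out.append(
                Violation(
                    path, "day-single-date",
                    f"day segment spans local dates {first}..{last}; each DayN must "
                    "lie within one midnight-to-midnight local day",
                )
            )
        dates.append(first)
    for prev, cur in zip(dates, dates[1:]):
        if (cur - prev).days != 1:
            out.append(
                Violation(
                    f"{base}/7-day", "days-consecutive",
                    f"Day dates must be consecutive local calendar days; got "
                    f"{prev} followed by {cur}",
                )
            )


def _first_timing(rec: Recording) -> TimingInfo | None:
    for unit in rec.sensor_units.values():
        for loc in unit.locations.values():
            return loc.timing
    return None
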