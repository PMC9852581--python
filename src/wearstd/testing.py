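"""Equality assertions for standardized datasets (NaN-aware, field-by-field).

Used by the test suite and available to downstream users for round-trip
checks.  Volatile ``dataset_info`` keys starting with an underscore (read
artifacts such as ``_warnings``) are ignored.
"""

from __future__ import annotations

import numpy as np

from . import goldstd as gs
from .schema import LocationData, Recording, SubjectDataset

__all__ = ["assert_datasets_equal", "assert_recordings_equal", "assert_locations_equal"]


def _arrays_equal(a, b, where: str) -> None:
    if a is None and b is None:
        return
    assert a is not None and b is not None, f"{where}: one side absent"
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    assert a.shape == b.shape, f"{where}: shapes {a.shape} != {b.shape}"
    np.testing.assert_array_equal(a, b, err_msg=where)  # NaN == NaN here


def assert_locations_equal(a: LocationData, b: LocationData, where: str = "") -> None:
    for attr in ("acc", "gyr", "mag", "bar", "temp", "quat"):
        _arrays_equal(getattr(a, attr), getattr(b, attr), f"{where}.{attr}")
    assert a.fs == b.fs, f"{where}.fs: {a.fs} != {b.fs}"
    ta, tb = a.timing, b.timing
    assert ta.start_date_time == tb.start_date_time, f"{where}.StartDateTime"
    assert ta.time_zone == tb.time_zone, f"{where}.TimeZone"
    assert ta.start_date_time_temp == tb.start_date_time_temp, f"{where}.StartDateTime_Temp"
    _arrays_equal(ta.timestamp, tb.timestamp, f"{where}.Timestamp")


def _strides_equal(a: gs.StrideAnnotation, b: gs.StrideAnnotation, where: str) -> None:
    assert (a.foot, a.start, a.end, a.final_contact, a.length, a.on_incline) == (
        b.foot, b.start, b.end, b.final_contact, b.length, b.on_incline
    ), f"{where}: {a} != {b}"


def _sequences_equal(a: gs.WalkingSequence, b: gs.WalkingSequence, where: str) -> None:
    assert a.kind == b.kind, f"{where}.kind"
    assert len(a.strides) == len(b.strides), f"{where}: stride counts differ"
    for i, (sa, sb) in enumerate(zip(a.strides, b.strides)):
        _strides_equal(sa, sb, f"{where}.stride[{i}]")
    assert a.turns == b.turns, f"{where}.turns"
    assert a.inclines == b.inclines, f"{where}.inclines"


def _standards_equal(a: gs.Standards, b: gs.Standards, where: str) -> None:
    assert set(a.systems) == set(b.systems), f"{where}: system names differ"
    for name in a.systems:
        ba, bb = a.systems[name], b.systems[name]
        w = f"{where}.{name}"
        assert ba.fs == bb.fs, f"{w}.Fs"
        assert set(ba.sequences) == set(bb.sequences), f"{w}: sequence kinds differ"
        for kind in ba.sequences:
            sa, sb = ba.sequences[kind], bb.sequences[kind]
            assert len(sa) == len(sb), f"{w}.{kind}: counts {len(sa)} != {len(sb)}"
            for i, (xa, xb) in enumerate(zip(sa, sb)):
                _sequences_equal(xa, xb, f"{w}.{kind}[{i}]")
        if ba.flag is None or bb.flag is None:
            assert ba.flag is None and bb.flag is None, f"{w}.Flag"
        else:
            np.testing.assert_array_equal(
                np.asarray(ba.flag, bool), np.asarray(bb.flag, bool), err_msg=f"{w}.Flag"
            )
        assert ba.gaps_percentage == bb.gaps_percentage, f"{w}.GapsPercentage"


def assert_recordings_equal(a: Recording, b: Recording, where: str = "") -> None:
    assert set(a.sensor_units) == set(b.sensor_units), f"{where}: sensor units differ"
    for key in a.sensor_units:
        ua, ub = a.sensor_units[key], b.sensor_units[key]
        assert set(ua.locations) == set(ub.locations), f"{where}.{key}: locations differ"
        for loc in ua.locations:
            assert_locations_equal(
                ua.locations[loc], ub.locations[loc], f"{where}.{key}.{loc}"
            )
    if a.standards is None or b.standards is None:
        assert a.standards is None and b.standards is None, f"{where}.Standards presence"
    else:
        _standards_equal(a.standards, b.standards, f"{where}.Standards")


def assert_datasets_equal(a: SubjectDataset, b: SubjectDataset) -> None:
    """Field-by-field equality of two subject datasets (read/write round trips)."""
    assert a.subject_id == b.subject_id
    assert list(a.time_measurements) == list(b.time_measurements), "T labels differ"
    for label in a.time_measurements:
        ta, tb = a.time_measurements[label], b.time_measurements[label]
        for part in ("laboratory", "free_living", "seven_day"):
            pa, pb = getattr(ta, part), getattr(tb, part)
            assert (pa is None) == (pb is None), f"{label}.{part} presence differs"
        if ta.laboratory is not None:
            la, lb = ta.laboratory, tb.laboratory
            assert list(la.tests) == list(lb.tests), f"{label}: test keys differ"
            assert la.names == lb.names, f"{label}: names differ"
            for tk in la.tests:
                assert list(la.tests[tk]) == list(lb.tests[tk]), f"{label}.{tk}"
                for rk in la.tests[tk]:
                    assert_recordings_equal(
                        la.tests[tk][rk], lb.tests[tk][rk], f"{label}/{tk}/{rk}"
                    )
        if ta.free_living is not None:
            assert_recordings_equal(
                ta.free_living.recording,
                tb.free_living.recording,
                f"{label}/Free-living",
            )
        if ta.seven_day is not None:
            assert len(ta.seven_day) == len(tb.seven_day), f"{label}: day counts differ"
            for i, (da, db) in enumerate(zip(ta.seven_day, tb.seven_day), start=1):
                assert_recordings_equal(
                    da.recording, db.recording, f"{label}/7-day/Day{i}"
                )
        assert ta.contextual_present == tb.contextual_present, f"{label}.Contextual"
    ia, ib = a.info_for_algo, b.info_for_algo
    assert (ia is None) == (ib is None), "info_for_algo presence differs"
    if ia is not None:
        assert (ia.sensor_type, ia.attachment, ia.walking_aid) == (
            ib.sensor_type, ib.attachment, ib.walking_aid
        )
        assert ia.anthropometrics == ib.anthropometrics
    pa = {k: v for k, v in a.dataset_info.items() if not k.startswith("_")}
    pb = {k: v for k, v in b.dataset_info.items() if not k.startswith("_")}
    assert pa == pb, f"dataset_info differs: {pa} != {pb}"
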