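"""Data-model construction and validation rules."""

import numpy as np
import pytest

from wearstd.schema import make_subject_id, validate
from wearstd.synthetic import FixtureSpec, generate_subject


@pytest.mark.parametrize(
    "site,participant,expected",
    [(1, 1, "1001"), (2, 34, "2034"), (9, 999, "9999"), (3, 7, "3007")],
)
def test_make_subject_id_composes_site_and_padded_participant(site, participant, expected):
    assert make_subject_id(site, participant) == expected


@pytest.mark.parametrize(
    "site,participant,field",
    [(0, 1, "site"), (10, 1, "site"), (1, 0, "participant"), (1, 1000, "participant")],
)
def test_make_subject_id_rejects_out_of_range(site, participant, field):
    with pytest.raises(ValueError, match=field):
        make_subject_id(site, participant)


def test_make_subject_id_is_injective_over_full_domain():
    ids = {make_subject_id(s, p) for s in range(1, 10) for p in range(1, 1000)}
    assert len(ids) == 9 * 999


@pytest.mark.parametrize("kind", ["free_living", "laboratory", "seven_day"])
def test_generated_fixtures_validate_cleanly(kind):
    dataset, _ = generate_subject(FixtureSpec(seed=7, kind=kind))
    assert validate(dataset, strict=True) == []


def _first_location(dataset):
    tm = dataset.time_measurements["T1"]
    return tm.free_living.recording.sensor_units["SU"].locations["LowerBack"]


def test_four_column_acc_yields_targeted_violation(free_living_fixture):
    _, dataset, _ = free_living_fixture
    loc = _first_location(dataset)
    loc.acc = np.hstack([loc.acc, loc.acc[:, :1]])
    rules = {(v.rule, "Acc" in v.path) for v in validate(dataset, strict=True)}
    assert ("acc-3-columns", True) in rules


def test_unknown_location_flagged_only_in_strict_mode(free_living_fixture):
    _, dataset, _ = free_living_fixture
    unit = dataset.time_measurements["T1"].free_living.recording.sensor_units["SU"]
    unit.locations["leftShank"] = unit.locations.pop("LowerBack")
    strict = validate(dataset, strict=True)
    assert any(v.rule == "location-registry" and "leftShank" in v.path for v in strict)
    assert not any(v.rule == "location-registry" for v in validate(dataset, strict=False))


def test_arbitrary_subject_id_allowed_only_in_non_strict_mode(free_living_fixture):
    _, dataset, _ = free_living_fixture
    dataset.subject_id = "ICICLE_HC01"
    assert any(v.rule == "subject-id-snnn" for v in validate(dataset, strict=True))
    assert validate(dataset, strict=False) == []


@pytest.mark.parametrize(
    "mutate,rule",
    [
        (lambda loc: loc.fs.pop("Gyr"), "fs-missing"),
        (lambda loc: loc.fs.__setitem__("Acc", 0.0), "fs-positive"),
        (
            lambda loc: setattr(loc.timing, "timestamp", loc.timing.timestamp[:-5]),
            "timestamp-length",
        ),
        (
            lambda loc: setattr(loc.timing, "start_date_time", "2023-05-15 09:30:00"),
            "iso8601-format",
        ),
        (
            lambda loc: setattr(loc.timing, "time_zone", "Mars/Olympus"),
            "iana-zone",
        ),
        (
            lambda loc: setattr(
                loc.timing, "start_date_time", "2023-05-15T09:30:00.001+02:00"
            ),
            "startdatetime-consistency",
        ),
    ],
)
def test_single_field_corruptions_are_caught(free_living_fixture, mutate, rule):
    _, dataset, _ = free_living_fixture
    mutate(_first_location(dataset))
    violations = validate(dataset, strict=True)
    assert any(v.rule == rule for v in violations), violations


def test_attachment_enum_enforced(free_living_fixture):
    _, dataset, _ = free_living_fixture
    dataset.info_for_algo.attachment = "glued-on"
    assert any(v.rule == "attachment-enum" for v in validate(dataset))


def test_non_consecutive_seven_day_dates_flagged():
    dataset, _ = generate_subject(FixtureSpec(seed=9, kind="seven_day", n_days=2))
    tm = dataset.time_measurements["T1"]
    # drop the middle day of a 3-day recording built by hand: shift Day2 by +2 days
    loc = tm.seven_day[1].recording.sensor_units["SU"].locations["LowerBack"]
    loc.timing.timestamp = loc.timing.timestamp + 86400.0
    from wearstd.timing import format_start_datetime

    loc.timing.start_date_time = format_start_datetime(
        float(loc.timing.timestamp[0]), loc.timing.time_zone
    )
    loc.timing.start_date_time_temp = loc.timing.start_date_time
    assert any(v.rule == "days-consecutive" for v in validate(dataset))
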