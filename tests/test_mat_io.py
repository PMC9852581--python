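"""Container round trips, raw-CSV ingestion, and folder-layout behavior."""

import shutil
import time

import numpy as np
import pytest

from wearstd.conventions import AxisMap
from wearstd.mat_io import (
    AlignmentError,
    DeviceDialect,
    DialectError,
    SchemaError,
    SensorDialect,
    ingest_raw_csv,
    read_subject,
    write_subject,
)
from wearstd.synthetic import (
    BoutSpec,
    FixtureSpec,
    default_dialect,
    export_raw,
    generate_subject,
)
from wearstd.testing import assert_datasets_equal, assert_locations_equal


@pytest.mark.parametrize("kind", ["free_living", "laboratory", "seven_day"])
@pytest.mark.parametrize("version", ["v7", "v7.3"])
def test_write_read_round_trip_all_kinds(tmp_path, kind, version):
    dataset, _ = generate_subject(
        FixtureSpec(seed=300, kind=kind, bouts=(BoutSpec(4.0, 6),), duration=15.0)
    )
    write_subject(dataset, tmp_path, container_version=version)
    assert_datasets_equal(dataset, read_subject(tmp_path / dataset.subject_id))


@pytest.mark.parametrize("version", ["v7", "v7.3"])
def test_round_trip_preserves_nan_and_optional_fields(tmp_path, version, small_spec):
    dataset, _ = generate_subject(small_spec)
    loc = dataset.time_measurements["T1"].free_living.recording.sensor_units[
        "SU"
    ].locations["LowerBack"]
    loc.acc[5:9, :] = np.nan
    loc.mag = None
    del loc.fs["Mag"]
    write_subject(dataset, tmp_path, container_version=version)
    back = read_subject(tmp_path / dataset.subject_id)
    assert_datasets_equal(dataset, back)
    loc2 = back.time_measurements["T1"].free_living.recording.sensor_units[
        "SU"
    ].locations["LowerBack"]
    assert loc2.mag is None
    assert np.isnan(loc2.acc[5:9, :]).all()


def test_two_device_types_become_su_and_su_suffix_nodes(tmp_path):
    import scipy.io as sio

    dataset, _ = generate_subject(
        FixtureSpec(seed=301, extra_device="INDIP", bouts=(BoutSpec(4.0, 4),), duration=12.0)
    )
    write_subject(dataset, tmp_path)
    raw = sio.loadmat(
        tmp_path / "1001" / "Free-living" / "data.mat", simplify_cells=True
    )
    assert {"SU", "SU_INDIP"} <= set(raw["data"])
    assert {"LeftFoot", "RightFoot"} <= set(raw["data"]["SU_INDIP"])
    back = read_subject(tmp_path / "1001")
    assert_datasets_equal(dataset, back)


def test_seven_day_dataset_writes_day_folders(tmp_path):
    dataset, _ = generate_subject(
        FixtureSpec(seed=302, kind="seven_day", n_days=3,
                    bouts=(BoutSpec(4.0, 4),), duration=12.0)
    )
    write_subject(dataset, tmp_path)
    days = sorted(p.name for p in (tmp_path / "1001" / "7-day").iterdir())
    assert days == ["Day1", "Day2", "Day3"]
    assert all((tmp_path / "1001" / "7-day" / d / "data.mat").exists() for d in days)


def test_missing_info_for_algo_yields_warning_not_error(tmp_path, small_spec):
    dataset, _ = generate_subject(small_spec)
    write_subject(dataset, tmp_path)
    for p in (tmp_path / dataset.subject_id).rglob("infoForAlgo.mat"):
        p.unlink()
    back = read_subject(tmp_path / dataset.subject_id)
    assert back.info_for_algo is None
    assert any("infoForAlgo" in w for w in back.dataset_info["_warnings"])


def test_empty_directory_is_a_schema_error(tmp_path):
    (tmp_path / "1001").mkdir()
    with pytest.raises(SchemaError):
        read_subject(tmp_path / "1001")


def test_unknown_sibling_files_listed_not_loaded(tmp_path, small_spec):
    dataset, _ = generate_subject(small_spec)
    write_subject(dataset, tmp_path)
    stray = tmp_path / dataset.subject_id / "Free-living" / "acc_raw_export.csv"
    stray.write_text("x,y,z\n")
    back = read_subject(tmp_path / dataset.subject_id)
    assert any("acc_raw_export.csv" in f for f in back.dataset_info["_unknown_files"])


def test_existing_subject_dir_requires_overwrite(tmp_path, small_spec):
    dataset, _ = generate_subject(small_spec)
    write_subject(dataset, tmp_path)
    with pytest.raises(FileExistsError):
        write_subject(dataset, tmp_path)
    write_subject(dataset, tmp_path, overwrite=True)  # replaces cleanly
    assert_datasets_equal(dataset, read_subject(tmp_path / dataset.subject_id))


@pytest.mark.parametrize("version", ["v7", "v7.3"])
def test_writes_are_byte_deterministic(tmp_path, version, small_spec):
    dataset, _ = generate_subject(small_spec)
    write_subject(dataset, tmp_path / "a", container_version=version)
    time.sleep(1.05)  # would surface any embedded wall-clock timestamps
    write_subject(dataset, tmp_path / "b", container_version=version)
    fa = tmp_path / "a" / "1001" / "Free-living" / "data.mat"
    fb = tmp_path / "b" / "1001" / "Free-living" / "data.mat"
    assert fa.read_bytes() == fb.read_bytes()


def test_multi_time_measurement_uses_explicit_t_dirs(tmp_path, small_spec):
    dataset, _ = generate_subject(small_spec)
    tm = dataset.time_measurements["T1"]
    dataset.time_measurements["T2"] = tm
    write_subject(dataset, tmp_path)
    assert (tmp_path / "1001" / "T1" / "Free-living" / "data.mat").exists()
    assert (tmp_path / "1001" / "T2" / "Free-living" / "data.mat").exists()
    back = read_subject(tmp_path / "1001")
    assert list(back.time_measurements) == ["T1", "T2"]
    assert_datasets_equal(dataset, back)


# ---------------------------------------------------------------------------
# raw CSV ingestion
# ---------------------------------------------------------------------------


def test_export_ingest_reproduces_standardized_signals(tmp_path, small_spec):
    files = export_raw(small_spec, tmp_path)
    loc = ingest_raw_csv(files, small_spec.dialect)
    dataset, _ = generate_subject(small_spec)
    truth = dataset.time_measurements["T1"].free_living.recording.sensor_units[
        "SU"
    ].locations["LowerBack"]
    for attr in ("acc", "gyr", "mag", "bar", "temp"):
        np.testing.assert_allclose(
            getattr(loc, attr), getattr(truth, attr), rtol=1e-12, atol=1e-12
        )
    assert loc.timing.start_date_time == truth.timing.start_date_time


def test_rad_per_s_gyro_is_scaled_to_deg_per_s(tmp_path, small_spec):
    files = export_raw(small_spec, tmp_path)
    import pandas as pd

    raw = pd.read_csv(files["gyr"], skiprows=1)
    device = raw[["x", "y", "z"]].to_numpy()
    loc = ingest_raw_csv({"gyr": files["gyr"], "acc": files["acc"]}, small_spec.dialect)
    inv = small_spec.dialect.axis_map.inverse()
    np.testing.assert_allclose(
        inv.apply(loc.gyr), device * (180.0 / np.pi), rtol=1e-12
    )


def test_missing_gyroscope_file_leaves_gyr_absent(tmp_path, small_spec):
    files = export_raw(small_spec, tmp_path)
    files.pop("gyr")
    loc = ingest_raw_csv(files, small_spec.dialect)
    assert loc.gyr is None and "Gyr" not in loc.fs
    assert loc.acc is not None


def test_inconsistent_row_counts_at_equal_fs_raise(tmp_path, small_spec):
    files = export_raw(small_spec, tmp_path)
    lines = files["gyr"].read_text().splitlines()
    files["gyr"].write_text("\n".join(lines[:-10]) + "\n")
    with pytest.raises(AlignmentError):
        ingest_raw_csv(files, small_spec.dialect)


def test_unknown_unit_is_a_dialect_error(tmp_path, small_spec):
    files = export_raw(small_spec, tmp_path)
    dialect = default_dialect()
    dialect.sensors["acc"] = SensorDialect(unit="furlong/s^2", fs=100.0,
                                           columns=["x", "y", "z"])
    from wearstd.conventions import UnitError

    with pytest.raises(UnitError):
        ingest_raw_csv(files, dialect)


def test_time_column_dialect_builds_timestamp_vector(tmp_path, small_spec):
    dialect = default_dialect()
    dialect.start_time_source = "column"
    spec = FixtureSpec(
        seed=small_spec.seed, bouts=small_spec.bouts, duration=small_spec.duration,
        dialect=dialect,
    )
    files = export_raw(spec, tmp_path)
    loc = ingest_raw_csv(files, dialect)
    assert loc.timing.timestamp is not None
    assert loc.timing.timestamp.shape[0] == loc.acc.shape[0]
    dataset, _ = generate_subject(spec)
    truth = dataset.time_measurements["T1"].free_living.recording.sensor_units[
        "SU"
    ].locations["LowerBack"]
    np.testing.assert_allclose(loc.timing.timestamp, truth.timing.timestamp, rtol=0, atol=1e-6)


def test_dialect_yaml_round_trip(tmp_path):
    dialect = default_dialect()
    path = tmp_path / "dialect.yaml"
    dialect.to_yaml(path)
    back = DeviceDialect.from_yaml(path)
    assert back.to_dict() == dialect.to_dict()


def test_left_handed_axis_map_rejected_in_dialect():
    with pytest.raises(Exception) as exc_info:
        DeviceDialect(
            name="bad",
            timezone="UTC",
            sensors={"acc": SensorDialect(unit="g", fs=100.0, columns=["x", "y", "z"])},
            axis_map=AxisMap(signs=(1, 1, -1)),
        )
    assert "determinant" in str(exc_info.value)
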