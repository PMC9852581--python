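"""Reading and writing standardized subject folders.

On disk, one subject is::

    <subject_id>/
        [T1/ T2/ ...]          # explicit only with multiple time measurements
            Laboratory/        # data.mat (+ infoForAlgo.mat)
            Free-living/       # data.mat (+ infoForAlgo.mat)
            7-day/Day1..DayN/  # one data.mat (+ infoForAlgo.mat) per local day
            Contextual/        # opaque, never parsed
        DatasetInfo.yaml       # free-text dataset metadata

``data.mat`` is a MATLAB container (classic v7 via scipy, or HDF5-based v7.3
via the bundled backend) holding one variable ``data``: for laboratory
protocols a ``Test1..TestN`` / ``Recording1..RecordingM`` hierarchy, for
continuous recordings the sensor-unit structure directly.  Field names follow
the standardized vocabulary exactly ("SU", "SU_<DeviceName>", "Acc", "Fs",
"Timestamp", "StartDateTime", "TimeZone", "Standards", "MicroWB", ...).

Raw per-signal CSV exports from a device are ingested through a declarative
:class:`DeviceDialect` (column labels, units, axis map, rate, start-time
source), so supporting a new device needs a config file, not code.
"""

from __future__ import annotations

import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import scipy.io as sio
import yaml

from . import goldstd as gs
from ._mat73 import load_mat73, save_mat73
from .conventions import AxisMap, convert_units
from .schema import (
    InfoForAlgo,
    LocationData,
    Recording,
    SensorUnit,
    SIGNAL_FIELDS,
    SubjectDataset,
    TimeMeasurement,
    TimingInfo,
    Type1Recording,
    Type2Recording,
)
from .timing import format_start_datetime, parse_start_datetime

__all__ = [
    "SchemaError",
    "DialectError",
    "AlignmentError",
    "DeviceDialect",
    "SensorDialect",
    "FolderLayout",
    "read_subject",
    "write_subject",
    "ingest_raw_csv",
]


class SchemaError(ValueError):
    """Container or folder does not have the expected structure."""


class DialectError(ValueError):
    """Device dialect config is inconsistent with the raw files."""


class AlignmentError(ValueError):
    """Equal-rate signals disagree on sample counts."""


_KIND_TO_MAT = {"acc": "Acc", "gyr": "Gyr", "mag": "Mag", "bar": "Bar", "temp": "Temp"}

# ---------------------------------------------------------------------------
# Device dialects
# ---------------------------------------------------------------------------


@dataclass
class SensorDialect:
    """Raw-file description of one sensor: column labels, unit, rate."""

    unit: str
    fs: float
    columns: list[str]


@dataclass
class DeviceDialect:
    """Declarative description of a device's raw per-signal CSV export."""

    name: str
    timezone: str
    sensors: dict[str, SensorDialect]
    axis_map: AxisMap = field(default_factory=AxisMap)
    start_time_source: str = "header"  # "header" | "column"
    time_column: str = "timestamp"
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.start_time_source not in ("header", "column"):
            raise DialectError(
                "start_time_source must be 'header' or 'column', got "
                f"{self.start_time_source!r}"
            )
        unknown = set(self.sensors) - set(_KIND_TO_MAT)
        if unknown:
            raise DialectError(
                f"unknown sensor kinds {sorted(unknown)}; expected a subset of "
                f"{sorted(_KIND_TO_MAT)}"
            )
        self.axis_map.check()

    @classmethod
    def from_dict(cls, cfg: dict) -> "DeviceDialect":
        sensors = {
            kind: SensorDialect(
                unit=str(sc["unit"]),
                fs=float(sc["fs"]),
                columns=[str(c) for c in sc.get("columns", [])],
            )
            for kind, sc in cfg.get("sensors", {}).items()
        }
        axis_map = cfg.get("axis_map")
        return cls(
            name=str(cfg.get("name", "unnamed")),
            timezone=str(cfg["timezone"]),
            sensors=sensors,
            axis_map=AxisMap.from_mapping(axis_map) if axis_map else AxisMap(),
            start_time_source=str(cfg.get("start_time_source", "header")),
            time_column=str(cfg.get("time_column", "timestamp")),
            delimiter=str(cfg.get("delimiter", ",")),
        )

    @classmethod
    def from_yaml(cls, path) -> "DeviceDialect":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise DialectError(f"dialect config {path} is not a mapping")
        return cls.from_dict(cfg)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "timezone": self.timezone,
            "start_time_source": self.start_time_source,
            "time_column": self.time_column,
            "delimiter": self.delimiter,
            "axis_map": self.axis_map.to_mapping(),
            "sensors": {
                kind: {"unit": sc.unit, "fs": sc.fs, "columns": list(sc.columns)}
                for kind, sc in self.sensors.items()
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _read_signal_csv(
    path: Path, dialect: DeviceDialect, sensor: SensorDialect
) -> tuple[np.ndarray, float | None, np.ndarray | None]:
    """Return (values, header start unix time or None, time column or None)."""
    import pandas as pd

    if not Path(path).exists():
        raise FileNotFoundError(f"raw signal file not found: {path}")
    start_unix: float | None = None
    skip = 0
    if dialect.start_time_source == "header":
        with open(path) as fh:
            first = fh.readline().strip()
        m = re.match(r"#\s*start_time\s*[:=]\s*(.+)$", first)
        if not m:
            raise DialectError(
                f"{path}: expected a '# start_time: <ISO-8601>' header line, "
                f"got {first!r}"
            )
        start_unix = parse_start_datetime(m.group(1).strip())
        skip = 1
    df = pd.read_csv(path, sep=dialect.delimiter, skiprows=skip)
    missing = [c for c in sensor.columns if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing columns {missing} (has {list(df.columns)})")
    values = df[sensor.columns].to_numpy(dtype=float)
    times = None
    if dialect.start_time_source == "column":
        if dialect.time_column not in df.columns:
            raise DialectError(f"{path}: missing time column {dialect.time_column!r}")
        times = df[dialect.time_column].to_numpy(dtype=float)
        start_unix = float(times[0])
    return values, start_unix, times


def ingest_raw_csv(
    signal_files: dict[str, Path], dialect: DeviceDialect
) -> LocationData:
    """Standardize raw per-signal CSV files into a :class:`LocationData`.

    Tri-axial signals are unit-normalized and axis-remapped into V/ML/AP;
    scalar sensors (barometer, temperature) are unit-normalized only.  The
    temperature stream keeps its own start time when it differs from the
    motion sensors'.
    """
    unknown = set(signal_files) - set(dialect.sensors)
    if unknown:
        raise DialectError(
            f"files given for sensors {sorted(unknown)} not described by "
            f"dialect {dialect.name!r}"
        )
    arrays: dict[str, np.ndarray] = {}
    starts: dict[str, float] = {}
    time_cols: dict[str, np.ndarray] = {}
    for kind, path in signal_files.items():
        sensor = dialect.sensors[kind]
        values, start, times = _read_signal_csv(Path(path), dialect, sensor)
        values = convert_units(values, sensor.unit, kind)
        if kind in ("acc", "gyr", "mag"):
            if values.ndim != 2 or values.shape[1] != 3:
                raise DialectError(
                    f"{path}: tri-axial sensor {kind!r} needs 3 columns, "
                    f"got shape {values.shape}"
                )
            values = dialect.axis_map.apply(values)
        else:
            values = values.ravel()
        arrays[kind] = values
        if start is not None:
            starts[kind] = start
        if times is not None:
            time_cols[kind] = times
    if "acc" not in arrays:
        raise DialectError("an accelerometer file is required")
    # equal-rate tri-axial sensors must agree on sample counts
    by_fs: dict[float, dict[str, int]] = {}
    for kind in ("acc", "gyr", "mag"):
        if kind in arrays:
            by_fs.setdefault(dialect.sensors[kind].fs, {})[kind] = len(arrays[kind])
    for fs, counts in by_fs.items():
        if len(set(counts.values())) > 1:
            raise AlignmentError(
                f"signals at {fs} Hz disagree on sample counts: {counts}"
            )
    t0 = starts.get("acc")
    if t0 is None:
        raise DialectError("no start time available for the accelerometer stream")
    zone = dialect.timezone
    t_temp = starts.get("temp")
    timing = TimingInfo(
        start_date_time=format_start_datetime(t0, zone),
        time_zone=zone,
        timestamp=time_cols.get("acc"),
        start_date_time_temp=(
            format_start_datetime(t_temp, zone)
            if t_temp is not None and t_temp != t0
            else None
        ),
    )
    fs = {
        _KIND_TO_MAT[kind]: float(dialect.sensors[kind].fs) for kind in arrays
    }
    return LocationData(
        acc=arrays["acc"],
        timing=timing,
        fs=fs,
        gyr=arrays.get("gyr"),
        mag=arrays.get("mag"),
        bar=arrays.get("bar"),
        temp=arrays.get("temp"),
    )


# ---------------------------------------------------------------------------
# Tree encoding (shared by both container backends)
# ---------------------------------------------------------------------------


def _encode_location(loc: LocationData) -> dict:
    d: dict[str, Any] = {}
    for attr, arr in loc.signals():
        d[SIGNAL_FIELDS[attr]] = np.asarray(arr, dtype=float)
    d["Fs"] = {k: float(v) for k, v in loc.fs.items()}
    ti = loc.timing
    if ti.timestamp is not None:
        d["Timestamp"] = np.asarray(ti.timestamp, dtype=float)
    d["StartDateTime"] = ti.start_date_time
    d["TimeZone"] = ti.time_zone
    if ti.start_date_time_temp is not None:
        d["StartDateTime_Temp"] = ti.start_date_time_temp
    return d


def _decode_location(d: dict, path: str) -> LocationData:
    def _tri(name: str) -> np.ndarray | None:
        if name not in d:
            return None
        return np.asarray(d[name], dtype=float).reshape(-1, 3)

    def _vec(name: str) -> np.ndarray | None:
        if name not in d:
            return None
        return np.atleast_1d(np.asarray(d[name], dtype=float)).ravel()

    if "Acc" not in d:
        raise SchemaError(f"{path}: location block has no 'Acc' field")
    fs_node = d.get("Fs", {})
    if not isinstance(fs_node, dict):
        raise SchemaError(f"{path}: 'Fs' must be a struct of per-sensor rates")
    quat = None
    if "Quat" in d:
        quat = np.asarray(d["Quat"], dtype=float).reshape(-1, 4)
    timing = TimingInfo(
        start_date_time=str(d.get("StartDateTime", "")),
        time_zone=str(d.get("TimeZone", "")),
        timestamp=_vec("Timestamp"),
        start_date_time_temp=(
            str(d["StartDateTime_Temp"]) if "StartDateTime_Temp" in d else None
        ),
    )
    return LocationData(
        acc=_tri("Acc"),
        timing=timing,
        fs={k: float(v) for k, v in fs_node.items()},
        gyr=_tri("Gyr"),
        mag=_tri("Mag"),
        bar=_vec("Bar"),
        temp=_vec("Temp"),
        quat=quat,
    )


def _encode_sequence(seq: gs.WalkingSequence) -> dict:
    p = seq.params if seq.params is not None else gs.compute_parameters(seq)
    strides = seq.strides
    d: dict[str, Any] = {
        "Start": float(p.start),
        "End": float(p.end),
        "Duration": float(p.duration),
        "Cadence": float(p.cadence),
        "NumberStrides": float(p.n_strides),
        "NumberStridesLeft": float(p.n_strides_left),
        "NumberStridesRight": float(p.n_strides_right),
        "Stride_Start": np.array([s.start for s in strides], dtype=float),
        "Stride_End": np.array([s.end for s in strides], dtype=float),
        "Stride_FinalContact": np.array(
            [np.nan if s.final_contact is None else s.final_contact for s in strides]
        ),
        "Stride_Length": np.array(
            [np.nan if s.length is None else s.length for s in strides]
        ),
        "Stride_Foot": "".join("L" if s.foot == "left" else "R" for s in strides),
        "Stride_OnIncline": np.array([s.on_incline for s in strides], dtype=bool),
    }
    if p.length is not None:
        d["Length"] = float(p.length)
    if p.stride_speed is not None:
        d["Stride_Speed"] = p.stride_speed
    if p.stance is not None:
        d["Stance"] = p.stance
        d["Swing"] = p.swing
    d["InitialContact"] = p.initial_contacts
    if p.final_contacts is not None:
        d["FinalContact"] = p.final_contacts
    if seq.turns:
        t = np.asarray(seq.turns, dtype=float).reshape(-1, 4)
        d["Turn_Start"], d["Turn_End"] = t[:, 0], t[:, 1]
        d["Turn_Duration"], d["Turn_Angle"] = t[:, 2], t[:, 3]
    if seq.inclines:
        t = np.asarray(seq.inclines, dtype=float).reshape(-1, 4)
        d["Incline_Start"], d["Incline_End"] = t[:, 0], t[:, 1]
        d["Incline_Duration"], d["Incline_Elevation"] = t[:, 2], t[:, 3]
    return d


def _decode_sequence(d: dict, kind: str) -> gs.WalkingSequence:
    starts = np.atleast_1d(np.asarray(d["Stride_Start"], dtype=float)).ravel()
    ends = np.atleast_1d(np.asarray(d["Stride_End"], dtype=float)).ravel()
    fcs = np.atleast_1d(np.asarray(d.get("Stride_FinalContact", np.nan), dtype=float))
    fcs = np.broadcast_to(fcs.ravel(), starts.shape)
    lens = np.atleast_1d(np.asarray(d.get("Stride_Length", np.nan), dtype=float))
    lens = np.broadcast_to(lens.ravel(), starts.shape)
    feet = str(d.get("Stride_Foot", ""))
    incl = np.atleast_1d(np.asarray(d.get("Stride_OnIncline", False))).astype(bool)
    incl = np.broadcast_to(incl.ravel(), starts.shape)
    strides = [
        gs.StrideAnnotation(
            foot="left" if feet[i] == "L" else "right",
            start=float(starts[i]),
            end=float(ends[i]),
            final_contact=None if np.isnan(fcs[i]) else float(fcs[i]),
            length=None if np.isnan(lens[i]) else float(lens[i]),
            on_incline=bool(incl[i]),
        )
        for i in range(starts.size)
    ]

    def _quad(prefix: str, last: str) -> list[tuple[float, float, float, float]]:
        if f"{prefix}_Start" not in d:
            return []
        cols = [
            np.atleast_1d(np.asarray(d[f"{prefix}_{f}"], dtype=float)).ravel()
            for f in ("Start", "End", "Duration", last)
        ]
        return [tuple(float(c[i]) for c in cols) for i in range(cols[0].size)]

    turns = _quad("Turn", "Angle")
    inclines = _quad("Incline", "Elevation")
    seq = gs.WalkingSequence(kind=kind, strides=strides, turns=turns, inclines=inclines)
    seq.params = gs.compute_parameters(seq)
    return seq


def _encode_standards(std: gs.Standards) -> dict:
    out: dict[str, Any] = {}
    for name, block in std.systems.items():
        b: dict[str, Any] = {"Fs": float(block.fs)}
        for kind in gs.SEQUENCE_KINDS:
            seqs = block.sequences.get(kind, [])
            if seqs:
                b[kind] = [_encode_sequence(s) for s in seqs]
        ann: dict[str, Any] = {}
        if block.flag is not None:
            ann["Flag"] = np.asarray(block.flag, dtype=bool)
        if block.gaps_percentage is not None:
            ann["GapsPercentage"] = float(block.gaps_percentage)
        if ann:
            b["Annotations"] = ann
        if block.raw is not None:
            b[f"{name}_raw"] = block.raw
        out[name] = b
    return out


def _decode_standards(d: dict, path: str) -> gs.Standards:
    std = gs.Standards()
    for name, b in d.items():
        if not isinstance(b, dict):
            raise SchemaError(f"{path}.{name}: gold-standard block is not a struct")
        sequences: dict[str, list[gs.WalkingSequence]] = {}
        for kind in gs.SEQUENCE_KINDS:
            if kind not in b:
                continue
            node = b[kind]
            elems = node if isinstance(node, list) else [node]
            sequences[kind] = [_decode_sequence(e, kind) for e in elems]
        ann = b.get("Annotations", {})
        flag = None
        if isinstance(ann, dict) and "Flag" in ann:
            flag = np.atleast_1d(np.asarray(ann["Flag"])).astype(bool).ravel()
        gaps = None
        if isinstance(ann, dict) and "GapsPercentage" in ann:
            gaps = float(ann["GapsPercentage"])
        std.systems[name] = gs.GoldStandardBlock(
            fs=float(b.get("Fs", 0.0)),
            sequences=sequences,
            flag=flag,
            gaps_percentage=gaps,
            raw=b.get(f"{name}_raw"),
        )
    return std


def _encode_recording(rec: Recording) -> dict:
    d: dict[str, Any] = {}
    for key, unit in rec.sensor_units.items():
        d[key] = {name: _encode_location(loc) for name, loc in unit.locations.items()}
    if rec.standards is not None:
        d["Standards"] = _encode_standards(rec.standards)
    return d


def _decode_recording(d: dict, path: str) -> Recording:
    rec = Recording()
    for key, node in d.items():
        if key == "Standards":
            rec.standards = _decode_standards(node, f"{path}.Standards")
            continue
        if key != "SU" and not key.startswith("SU_"):
            raise SchemaError(
                f"{path}: unexpected node {key!r} (expected 'SU', 'SU_<Device>' "
                "or 'Standards')"
            )
        if not isinstance(node, dict):
            raise SchemaError(f"{path}.{key}: sensor unit is not a struct")
        unit = SensorUnit()
        for loc_name, loc_node in node.items():
            unit.locations[loc_name] = _decode_location(
                loc_node, f"{path}.{key}.{loc_name}"
            )
        rec.sensor_units[key] = unit
    return rec


def _encode_type1(t1: Type1Recording) -> dict:
    d: dict[str, Any] = {}
    for test_key, trials in t1.tests.items():
        d[test_key] = {
            trial_key: _encode_recording(rec) for trial_key, rec in trials.items()
        }
    names: dict[str, Any] = {}
    for key, label in t1.names.items():
        if "/" in key:
            test_key, trial_key = key.split("/", 1)
            names.setdefault(test_key, {})[trial_key] = label
        else:
            names.setdefault(key, {})["Test"] = label
    if names:
        d["Names"] = names
    return d


def _decode_type1(d: dict, path: str) -> Type1Recording:
    t1 = Type1Recording()
    names_node = d.get("Names", {})
    for test_key in _ordinal_sorted(k for k in d if k != "Names"):
        trials_node = d[test_key]
        if not isinstance(trials_node, dict):
            raise SchemaError(f"{path}.{test_key}: test node is not a struct")
        t1.tests[test_key] = {
            trial_key: _decode_recording(
                trials_node[trial_key], f"{path}.{test_key}.{trial_key}"
            )
            for trial_key in _ordinal_sorted(trials_node)
        }
    if isinstance(names_node, dict):
        for test_key, entry in names_node.items():
            if not isinstance(entry, dict):
                continue
            for sub_key, label in entry.items():
                key = test_key if sub_key == "Test" else f"{test_key}/{sub_key}"
                t1.names[key] = str(label)
    return t1


def _ordinal_sorted(keys) -> list[str]:
    def sort_key(k: str):
        m = re.search(r"(\d+)$", k)
        return (re.sub(r"\d+$", "", k), int(m.group(1)) if m else 0)

    return sorted(keys, key=sort_key)


def _encode_info(info: InfoForAlgo) -> dict:
    d: dict[str, Any] = {}
    if info.sensor_type is not None:
        d["SensorType"] = info.sensor_type
    if info.attachment is not None:
        d["Attachment"] = info.attachment
    if info.walking_aid is not None:
        d["WalkingAid"] = np.array([info.walking_aid], dtype=bool)
    if info.anthropometrics:
        d["Anthropometrics"] = {k: float(v) for k, v in info.anthropometrics.items()}
    for k, v in info.extras.items():
        d.setdefault(k, v)
    return d


def _decode_info(d: dict) -> InfoForAlgo:
    info = InfoForAlgo()
    for key, value in d.items():
        if key == "SensorType":
            info.sensor_type = str(value)
        elif key == "Attachment":
            info.attachment = str(value)
        elif key == "WalkingAid":
            arr = np.atleast_1d(np.asarray(value))
            info.walking_aid = bool(arr.ravel()[0])
        elif key == "Anthropometrics" and isinstance(value, dict):
            info.anthropometrics = {k: float(v) for k, v in value.items()}
        else:
            info.extras[key] = value
    return info


# ---------------------------------------------------------------------------
# Container backends
# ---------------------------------------------------------------------------

_V7_HEADER = (
    b"MATLAB 5.0 MAT-file, Platform: PCWIN64, Created by: wearstd".ljust(116, b" ")
)


def _to_scipy(node):
    if isinstance(node, dict):
        return {k: _to_scipy(v) for k, v in node.items()}
    if isinstance(node, list):
        fields: list[str] = []
        for e in node:
            for k in e:
                if k not in fields:
                    fields.append(k)
        arr = np.empty((1, len(node)), dtype=[(f, object) for f in fields])
        for i, e in enumerate(node):
            for f in fields:
                arr[0, i][f] = _to_scipy(e[f]) if f in e else np.zeros((0, 0))
        return arr
    return node


def _save_mat7(path, variables: dict) -> None:
    sio.savemat(
        path,
        {k: _to_scipy(v) for k, v in variables.items()},
        format="5",
        long_field_names=True,
        do_compression=True,
        oned_as="column",
    )
    with open(path, "r+b") as fh:  # fixed free-text header => deterministic bytes
        fh.write(_V7_HEADER)


def _normalize_loaded(node):
    """Coerce scipy's simplify_cells output into the shared tree shapes."""
    if isinstance(node, dict):
        return {k: _normalize_loaded(v) for k, v in node.items()}
    if isinstance(node, list):
        return [_normalize_loaded(v) for v in node]
    if isinstance(node, np.ndarray):
        if node.dtype == object:
            return [_normalize_loaded(v) for v in node.ravel()]
        if node.dtype.kind in "US":
            return str(node)
        if node.dtype == bool:
            return node
        arr = node.astype(float)
        return float(arr) if arr.ndim == 0 else arr
    if isinstance(node, (bool, np.bool_)):
        return bool(node)
    if isinstance(node, (int, float, np.integer, np.floating)):
        return float(node)
    return node


def _load_mat(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"container not found: {path}")
    try:
        if h5py.is_hdf5(str(path)):
            return load_mat73(path)
        raw = sio.loadmat(str(path), simplify_cells=True)
    except (OSError, ValueError) as exc:
        raise OSError(f"unreadable container {path}: {exc}") from exc
    return {
        k: _normalize_loaded(v) for k, v in raw.items() if not k.startswith("__")
    }


def _save_mat(path, variables: dict, container_version: str) -> None:
    if container_version == "v7":
        _save_mat7(path, variables)
    elif container_version in ("v7.3", "v73"):
        save_mat73(path, variables)
    else:
        raise ValueError(
            f"container_version must be 'v7' or 'v7.3', got {container_version!r}"
        )


# ---------------------------------------------------------------------------
# Folder layer
# ---------------------------------------------------------------------------


@dataclass
class FolderLayout:
    """Where a written subject landed on disk."""

    root: Path
    subject_id: str
    subject_dir: Path
    data_files: list[Path] = field(default_factory=list)


_RECORDING_DIRS = ("Laboratory", "Free-living", "7-day", "Contextual")


def write_subject(
    dataset: SubjectDataset,
    path,
    container_version: str = "v7",
    overwrite: bool = False,
    time_dirs: bool | None = None,
) -> FolderLayout:
    """Write a subject folder tree; returns the resulting layout.

    ``container_version`` selects classic MAT v7 or HDF5-based v7.3 for every
    ``data.mat`` / ``infoForAlgo.mat``.  Explicit T1..Tn directories are
    created only for multi-time-measurement datasets unless *time_dirs*
    forces the choice.  Validation violations never block writing.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    subject_dir = root / dataset.subject_id
    if subject_dir.exists():
        if not overwrite:
            raise FileExistsError(
                f"subject directory {subject_dir} already exists "
                "(pass overwrite=True to replace it)"
            )
        shutil.rmtree(subject_dir)
    subject_dir.mkdir()
    layout = FolderLayout(root=root, subject_id=dataset.subject_id, subject_dir=subject_dir)
    explicit = time_dirs if time_dirs is not None else len(dataset.time_measurements) > 1
    info_tree = (
        _encode_info(dataset.info_for_algo)
        if dataset.info_for_algo is not None
        else None
    )

    def _write_pair(rec_dir: Path, data_var) -> None:
        rec_dir.mkdir(parents=True, exist_ok=True)
        data_path = rec_dir / "data.mat"
        _save_mat(data_path, {"data": data_var}, container_version)
        layout.data_files.append(data_path)
        if info_tree is not None:
            _save_mat(rec_dir / "infoForAlgo.mat", {"infoForAlgo": info_tree}, container_version)

    for label, tm in dataset.time_measurements.items():
        base = subject_dir / label if explicit else subject_dir
        if tm.laboratory is not None:
            _write_pair(base / "Laboratory", _encode_type1(tm.laboratory))
        if tm.free_living is not None:
            _write_pair(
                base / "Free-living", _encode_recording(tm.free_living.recording)
            )
        if tm.seven_day is not None:
            for i, day in enumerate(tm.seven_day, start=1):
                _write_pair(
                    base / "7-day" / f"Day{i}", _encode_recording(day.recording)
                )
        if tm.contextual_present:
            (base / "Contextual").mkdir(parents=True, exist_ok=True)
    public_info = {
        k: v for k, v in dataset.dataset_info.items() if not k.startswith("_")
    }
    if public_info:
        with open(subject_dir / "DatasetInfo.yaml", "w") as fh:
            yaml.safe_dump(public_info, fh, sort_keys=False)
    return layout


def read_subject(path) -> SubjectDataset:
    """Load a standardized subject folder into a :class:`SubjectDataset`.

    Unknown sibling files are recorded under ``dataset_info['_unknown_files']``
    and never loaded; a missing ``infoForAlgo.mat`` yields a warning record in
    ``dataset_info['_warnings']`` instead of an error.  Signal values are
    passed through untouched (no recoding or resampling).
    """
    subject_dir = Path(path)
    if not subject_dir.is_dir():
        raise FileNotFoundError(f"subject directory not found: {subject_dir}")
    dataset = SubjectDataset(subject_id=subject_dir.name)
    warnings: list[str] = []
    unknown: list[str] = []

    t_dirs = sorted(
        (d for d in subject_dir.iterdir() if d.is_dir() and re.match(r"^T\d+$", d.name)),
        key=lambda d: int(d.name[1:]),
    )
    bases = [(d.name, d) for d in t_dirs] if t_dirs else [("T1", subject_dir)]

    info_read = False
    found_any = False
    for label, base in bases:
        tm = TimeMeasurement()
        lab_dir = base / "Laboratory"
        if (lab_dir / "data.mat").exists():
            found_any = True
            tree = _load_mat(lab_dir / "data.mat")
            tm.laboratory = _decode_type1(
                _expect_data(tree, lab_dir), f"{label}/Laboratory"
            )
        fl_dir = base / "Free-living"
        if (fl_dir / "data.mat").exists():
            found_any = True
            tree = _load_mat(fl_dir / "data.mat")
            tm.free_living = Type2Recording(
                _decode_recording(_expect_data(tree, fl_dir), f"{label}/Free-living")
            )
        sd_dir = base / "7-day"
        if sd_dir.is_dir():
            day_dirs = sorted(
                (
                    d
                    for d in sd_dir.iterdir()
                    if d.is_dir() and re.match(r"^Day\d+$", d.name)
                ),
                key=lambda d: int(d.name[3:]),
            )
            days = []
            for day_dir in day_dirs:
                if not (day_dir / "data.mat").exists():
                    warnings.append(f"{day_dir} has no data.mat; skipped")
                    continue
                found_any = True
                tree = _load_mat(day_dir / "data.mat")
                days.append(
                    Type2Recording(
                        _decode_recording(
                            _expect_data(tree, day_dir), f"{label}/7-day/{day_dir.name}"
                        )
                    )
                )
            if days:
                tm.seven_day = days
        tm.contextual_present = (base / "Contextual").is_dir()
        if any((tm.laboratory, tm.free_living, tm.seven_day, tm.contextual_present)):
            dataset.time_measurements[label] = tm
        # infoForAlgo: first one found anywhere in this subject
        if not info_read:
            for rec_dir in (lab_dir, fl_dir, *sorted(sd_dir.glob("Day*"))):
                info_path = rec_dir / "infoForAlgo.mat"
                if info_path.exists():
                    tree = _load_mat(info_path)
                    node = tree.get("infoForAlgo")
                    if isinstance(node, dict):
                        dataset.info_for_algo = _decode_info(node)
                        info_read = True
                        break
        unknown.extend(_unknown_files(base, explicit_t=bool(t_dirs)))

    if not found_any:
        raise SchemaError(
            f"{subject_dir} contains no recognized recording directory "
            "(Laboratory, Free-living or 7-day/DayN with a data.mat)"
        )
    if not info_read:
        warnings.append("no infoForAlgo.mat found; info_for_algo left absent")
    info_yaml = subject_dir / "DatasetInfo.yaml"
    if info_yaml.exists():
        with open(info_yaml) as fh:
            loaded = yaml.safe_load(fh)
        if isinstance(loaded, dict):
            dataset.dataset_info.update(loaded)
    if warnings:
        dataset.dataset_info["_warnings"] = warnings
    if unknown:
        dataset.dataset_info["_unknown_files"] = sorted(set(unknown))
    return dataset


def _expect_data(tree: dict, where: Path) -> dict:
    if "data" not in tree:
        present = sorted(tree)
        raise SchemaError(
            f"{where / 'data.mat'}: no 'data' variable (found {present})"
        )
    node = tree["data"]
    if not isinstance(node, dict):
        raise SchemaError(f"{where / 'data.mat'}: 'data' is not a struct")
    return node


def _unknown_files(base: Path, explicit_t: bool) -> list[str]:
    out = []
    known_here = set(_RECORDING_DIRS) | {"DatasetInfo.yaml"}
    for child in base.iterdir():
        if child.is_dir():
            if child.name in _RECORDING_DIRS or re.match(r"^T\d+$", child.name):
                continue
            out.append(str(child))
        elif child.name not in known_here:
            out.append(str(child))
    for sub in ("Laboratory", "Free-living"):
        d = base / sub
        if d.is_dir():
            out.extend(
                str(c)
                for c in d.iterdir()
                if c.name not in ("data.mat", "infoForAlgo.mat")
            )
    sd = base / "7-day"
    if sd.is_dir():
        for day in sd.iterdir():
            if day.is_dir() and re.match(r"^Day\d+$", day.name):
                out.extend(
                    str(c)
                    for c in day.iterdir()
                    if c.name not in ("data.mat", "infoForAlgo.mat")
                )
            elif day.is_dir() or day.name != ".DS_Store":
                out.append(str(day))
    return out
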