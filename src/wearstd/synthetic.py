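"""Deterministic, seeded fixtures: subjects, signals, strides, raw exports.

The generator emulates the data the standardization procedure is applied to:
a lower-back IMU (optionally with further device types), gold-standard stride
annotations with controllable breaks / incline / spurious-bout structure,
marker-occlusion flags, and raw per-signal CSV device exports.  Signal realism
is deliberately minimal — a periodic per-stride template plus seeded Gaussian
noise, with the gravity offset on the vertical accelerometer channel — since
the format governs storage, not biomechanics: fixtures need correct
structure, timing, units and axes, not plausible gait dynamics.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
spec; identical seeds give identical output.  The expected MicroWB / CWP
segmentation carried in :class:`GroundTruth` comes from the exhaustive
interval-enumeration oracle, not from the production builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import goldstd as gs
from ._oracle import intervals_of, oracle_cwp_intervals, oracle_micro_wb_intervals
from .conventions import AxisMap, convert_units_inverse
from .mat_io import DeviceDialect, SensorDialect
from .schema import (
    InfoForAlgo,
    LocationData,
    Recording,
    SensorUnit,
    SubjectDataset,
    TimeMeasurement,
    TimingInfo,
    Type1Recording,
    Type2Recording,
)
from .timing import format_start_datetime, parse_start_datetime

__all__ = [
    "BoutSpec",
    "FixtureSpec",
    "GroundTruth",
    "RecordingTruth",
    "generate_subject",
    "generate_recording",
    "export_raw",
    "default_dialect",
    "random_stride_list",
]


@dataclass(frozen=True)
class BoutSpec:
    """One scripted walking bout: alternating-foot strides from ``start``."""

    start: float  # seconds from recording start
    n_strides: int
    stride_duration: float = 1.0  # s
    stride_length: float = 1.25  # m
    incline_strides: tuple[int, ...] = ()  # bout-local indices on an incline
    first_foot: str = "left"

    def strides(self) -> list[gs.StrideAnnotation]:
        feet = ("left", "right") if self.first_foot == "left" else ("right", "left")
        d = self.stride_duration
        out = []
        for i in range(self.n_strides):
            s = self.start + i * d / 2.0  # contralateral contacts half a cycle apart
            out.append(
                gs.StrideAnnotation(
                    foot=feet[i % 2],
                    start=s,
                    end=s + d,
                    final_contact=s + 0.6 * d,  # 60 % stance, 40 % swing
                    length=self.stride_length,
                    on_incline=i in self.incline_strides,
                )
            )
        return out

    @property
    def end(self) -> float:
        return self.start + (self.n_strides + 1) * self.stride_duration / 2.0


#: Default free-living script: a clean 10-stride bout; after a 5 s break a
#: 2-stride spurious bout; after another break a bout whose middle strides
#: climb an incline.  Exercises every MicroWB exclusion rule.
DEFAULT_BOUTS: tuple[BoutSpec, ...] = (
    BoutSpec(start=10.0, n_strides=10),
    BoutSpec(start=21.5, n_strides=2),
    BoutSpec(start=30.0, n_strides=12, incline_strides=(5, 6)),
)


def default_dialect() -> DeviceDialect:
    """Raw-export dialect of the emulated device.

    Device frame: x forward (AP), y up (V), z right (ML) — a right-handed
    frame whose map to (V, ML, AP) has determinant +1.  Raw units are SI
    (m/s^2, rad/s); start time travels in a '# start_time:' header line.
    """
    return DeviceDialect(
        name="synthetic-device",
        timezone="Europe/Berlin",
        sensors={
            "acc": SensorDialect(unit="m/s^2", fs=100.0, columns=["x", "y", "z"]),
            "gyr": SensorDialect(unit="rad/s", fs=100.0, columns=["x", "y", "z"]),
            "mag": SensorDialect(unit="uT", fs=100.0, columns=["x", "y", "z"]),
            "bar": SensorDialect(unit="Pa", fs=25.0, columns=["p"]),
            "temp": SensorDialect(unit="degC", fs=1.0, columns=["t"]),
        },
        axis_map=AxisMap.from_mapping({"V": "y", "ML": "z", "AP": "x"}),
        start_time_source="header",
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Everything needed to generate one subject deterministically."""

    seed: int = 0
    subject_id: str = "1001"
    kind: str = "free_living"  # "laboratory" | "free_living" | "seven_day"
    n_days: int = 3
    zone: str = "Europe/Berlin"
    start_date_time: str = "2023-05-15T09:30:00.000+02:00"
    fs: dict[str, float] = field(
        default_factory=lambda: {
            "Acc": 100.0, "Gyr": 100.0, "Mag": 100.0, "Bar": 25.0, "Temp": 1.0
        }
    )
    duration: float | None = None  # seconds; default: last bout end + 10 s
    bouts: tuple[BoutSpec, ...] = DEFAULT_BOUTS
    occlusion_rate: float = 0.02
    with_timestamp: bool = True
    sensors: tuple[str, ...] = ("acc", "gyr", "mag", "bar", "temp")
    systems: tuple[str, ...] = ("Stereophoto",)
    extra_device: str | None = None  # e.g. "INDIP": adds SU_<name> foot units
    dialect: DeviceDialect = field(default_factory=default_dialect)

    def __post_init__(self) -> None:
        if not 0.0 <= self.occlusion_rate <= 1.0:
            raise ValueError(f"occlusion_rate must be in [0, 1], got {self.occlusion_rate}")
        ivs = sorted((b.start, b.end) for b in self.bouts)
        for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(
                    f"bout intervals overlap: one ends at {e0}s, next starts at {s1}s"
                )
        if self.kind not in ("laboratory", "free_living", "seven_day"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


@dataclass
class RecordingTruth:
    """Exact ground truth for one generated recording."""

    strides: list[gs.StrideAnnotation]
    micro_wb_intervals: list[tuple[float, ...]]  # stride-start fingerprints
    cwp_intervals: list[tuple[float, ...]]
    flag: np.ndarray | None
    gaps_percentage: float | None


@dataclass
class GroundTruth:
    """Per-recording truths keyed by path label ('Free-living', '7-day/Day1', ...)."""

    recordings: dict[str, RecordingTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def _stride_envelope(t: np.ndarray, strides: Sequence[gs.StrideAnnotation], freq_mult: float) -> np.ndarray:
    """Sum of per-stride sinusoid templates evaluated on time grid *t*."""
    out = np.zeros_like(t)
    for s in strides:
        m = (t >= s.start) & (t < s.end)
        cyc = (t[m] - s.start) / (s.end - s.start)
        out[m] += np.sin(2.0 * np.pi * freq_mult * cyc)
    return out


def _make_location(
    spec: FixtureSpec,
    rng: np.random.Generator,
    strides: Sequence[gs.StrideAnnotation],
    duration: float,
    t0: float,
) -> LocationData:
    fs_acc = spec.fs["Acc"]
    n = int(round(duration * fs_acc))
    t = np.arange(n) / fs_acc  # recording-relative seconds
    arrays: dict[str, np.ndarray] = {}
    if "acc" in spec.sensors:
        acc = np.empty((n, 3))
        acc[:, 0] = 1.0 + 0.35 * _stride_envelope(t, strides, 2.0)  # V: gravity + steps
        acc[:, 1] = 0.15 * _stride_envelope(t, strides, 1.0)  # ML sway
        acc[:, 2] = 0.25 * _stride_envelope(t, strides, 2.0)  # AP propulsion
        acc += rng.normal(0.0, 0.02, size=acc.shape)
        arrays["acc"] = acc
    if "gyr" in spec.sensors:
        n_g = int(round(duration * spec.fs["Gyr"]))
        tg = np.arange(n_g) / spec.fs["Gyr"]
        gyr = np.empty((n_g, 3))
        gyr[:, 0] = 8.0 * _stride_envelope(tg, strides, 1.0)  # yaw wobble
        gyr[:, 1] = 60.0 * _stride_envelope(tg, strides, 1.0)  # ML: pitch cycle
        gyr[:, 2] = 10.0 * _stride_envelope(tg, strides, 2.0)
        gyr += rng.normal(0.0, 1.0, size=gyr.shape)
        arrays["gyr"] = gyr
    if "mag" in spec.sensors:
        n_m = int(round(duration * spec.fs["Mag"]))
        mag = np.tile(np.array([-44.0, 1.5, 20.0]), (n_m, 1))  # V/ML/AP field, uT
        mag += rng.normal(0.0, 0.3, size=mag.shape)
        arrays["mag"] = mag
    if "bar" in spec.sensors:
        n_b = int(round(duration * spec.fs["Bar"]))
        tb = np.arange(n_b) / spec.fs["Bar"]
        arrays["bar"] = 1013.0 + 0.2 * np.sin(2 * np.pi * tb / 600.0) + rng.normal(
            0.0, 0.03, size=n_b
        )
    if "temp" in spec.sensors:
        n_t = max(1, int(round(duration * spec.fs["Temp"])))
        tt = np.arange(n_t) / spec.fs["Temp"]
        arrays["temp"] = 31.5 + 0.8 * (1 - np.exp(-tt / 300.0)) + rng.normal(
            0.0, 0.05, size=n_t
        )
    timing = TimingInfo(
        start_date_time=format_start_datetime(t0, spec.zone),
        time_zone=spec.zone,
        timestamp=(t0 + t if spec.with_timestamp and "acc" in arrays else None),
        start_date_time_temp=(
            format_start_datetime(t0, spec.zone) if "temp" in arrays else None
        ),
    )
    mat_names = {"acc": "Acc", "gyr": "Gyr", "mag": "Mag", "bar": "Bar", "temp": "Temp"}
    fs = {mat_names[k]: spec.fs[mat_names[k]] for k in arrays}
    return LocationData(
        acc=arrays.get("acc"),
        timing=timing,
        fs=fs,
        gyr=arrays.get("gyr"),
        mag=arrays.get("mag"),
        bar=arrays.get("bar"),
        temp=arrays.get("temp"),
    )


def _truth_for(
    spec: FixtureSpec,
    rng: np.random.Generator,
    strides: list[gs.StrideAnnotation],
    duration: float,
) -> tuple[gs.Standards | None, RecordingTruth]:
    flag = None
    gaps = None
    std = None
    if spec.systems:
        std = gs.Standards()
        fs_std = spec.fs.get("Acc", 100.0)
        n_std = int(round(duration * fs_std))
        for name in spec.systems:
            block = gs.GoldStandardBlock(fs=fs_std)
            kinds = gs.SYSTEM_SEQUENCE_KINDS.get(name, ("ContinuousWalkingPeriod",))
            if "MicroWB" in kinds:
                mwbs = [
                    gs.WalkingSequence("MicroWB", list(chunk), params=None)
                    for chunk in oracle_micro_wb_intervals(strides)
                ]
                if mwbs:
                    block.sequences["MicroWB"] = mwbs
            if "ContinuousWalkingPeriod" in kinds:
                cwps = [
                    gs.WalkingSequence("ContinuousWalkingPeriod", list(chunk), params=None)
                    for chunk in oracle_cwp_intervals(strides)
                ]
                if cwps:
                    block.sequences["ContinuousWalkingPeriod"] = cwps
            if "Pass" in kinds and strides:
                block.sequences["Pass"] = gs.build_passes(
                    strides, (strides[0].start, strides[-1].end), with_params=False
                )
            for seqs in block.sequences.values():
                for seq in seqs:
                    seq.params = gs.compute_parameters(seq)
            if name == "Stereophoto":
                # exactly round(rate * N) occluded samples at random positions
                k = int(round(spec.occlusion_rate * n_std))
                f = np.zeros(n_std, dtype=bool)
                if k:
                    f[rng.choice(n_std, size=k, replace=False)] = True
                block.flag = f
                block.gaps_percentage = gs.compute_gaps_percentage(f)
                flag, gaps = f, block.gaps_percentage
            std.systems[name] = block
    truth = RecordingTruth(
        strides=list(strides),
        micro_wb_intervals=intervals_of(oracle_micro_wb_intervals(strides)),
        cwp_intervals=intervals_of(oracle_cwp_intervals(strides)),
        flag=flag,
        gaps_percentage=gaps,
    )
    return std, truth


def generate_recording(
    spec: FixtureSpec,
    rng: np.random.Generator,
    t0: float,
    bouts: Sequence[BoutSpec] | None = None,
) -> tuple[Recording, RecordingTruth]:
    """One continuous recording starting at Unix time *t0*."""
    bouts = spec.bouts if bouts is None else tuple(bouts)
    strides = sorted(
        (s for b in bouts for s in b.strides()), key=lambda s: (s.start, s.end)
    )
    duration = spec.duration
    if duration is None:
        duration = (max(b.end for b in bouts) if bouts else 20.0) + 10.0
    std, truth = _truth_for(spec, rng, strides, duration)
    unit = SensorUnit(
        locations={"LowerBack": _make_location(spec, rng, strides, duration, t0)}
    )
    rec = Recording(sensor_units={"SU": unit}, standards=std)
    if spec.extra_device:
        extra = SensorUnit()
        for loc in ("LeftFoot", "RightFoot"):
            extra.locations[loc] = _make_location(spec, rng, strides, duration, t0)
        rec.sensor_units[f"SU_{spec.extra_device}"] = extra
    return rec, truth


def generate_subject(spec: FixtureSpec) -> tuple[SubjectDataset, GroundTruth]:
    """Build a complete subject dataset plus its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    t0 = parse_start_datetime(spec.start_date_time)
    tm = TimeMeasurement()
    truth = GroundTruth()
    if spec.kind == "free_living":
        rec, rt = generate_recording(spec, rng, t0)
        tm.free_living = Type2Recording(rec)
        truth.recordings["Free-living"] = rt
    elif spec.kind == "laboratory":
        t1 = Type1Recording()
        t1.names["Test1"] = "Straight walking"
        t1.names["Test2"] = "Walking with incline"
        layout = [("Test1", 2), ("Test2", 1)]
        offset = 0.0
        for test_key, n_trials in layout:
            trials: dict[str, Recording] = {}
            for j in range(1, n_trials + 1):
                rec, rt = generate_recording(spec, rng, t0 + offset)
                trials[f"Recording{j}"] = rec
                truth.recordings[f"Laboratory/{test_key}/Recording{j}"] = rt
                offset += (spec.duration or 60.0) + 120.0
            t1.tests[test_key] = trials
        tm.laboratory = t1
    else:  # seven_day
        day_len = 86400.0
        for d in range(spec.n_days):
            rec, rt = generate_recording(spec, rng, t0 + d * day_len)
            tm.seven_day = (tm.seven_day or []) + [Type2Recording(rec)]
            truth.recordings[f"7-day/Day{d + 1}"] = rt
    dataset = SubjectDataset(
        subject_id=spec.subject_id,
        time_measurements={"T1": tm},
        info_for_algo=InfoForAlgo(
            sensor_type="TriaxialIMU",
            attachment="body-worn",
            anthropometrics={"Height": 1.72, "Weight": 70.0},
            walking_aid=False,
        ),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# raw CSV export (inverse of mat_io.ingest_raw_csv)
# ---------------------------------------------------------------------------


def export_raw(spec: FixtureSpec, out: Path) -> dict[str, Path]:
    """Write the fixture's signals as raw per-signal device CSVs.

    Values are mapped back into the device's own frame and units (inverse
    axis map, inverse unit conversion), so that
    :func:`wearstd.mat_io.ingest_raw_csv` reproduces the standardized signals.
    Returns the sensor -> file map expected by the ingest routine.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    t0 = parse_start_datetime(spec.start_date_time)
    rec, _ = generate_recording(spec, rng, t0)
    loc = rec.sensor_units["SU"].locations["LowerBack"]
    dialect = spec.dialect
    inv = dialect.axis_map.inverse()
    start_iso = format_start_datetime(t0, dialect.timezone)
    paths: dict[str, Path] = {}
    attr_map = {"acc": loc.acc, "gyr": loc.gyr, "mag": loc.mag, "bar": loc.bar, "temp": loc.temp}
    for kind, arr in attr_map.items():
        if arr is None or kind not in dialect.sensors:
            continue
        sensor = dialect.sensors[kind]
        if kind in ("acc", "gyr", "mag"):
            device_vals = convert_units_inverse(inv.apply(arr), sensor.unit, kind)
        else:
            device_vals = convert_units_inverse(arr, sensor.unit, kind).reshape(-1, 1)
        path = out / f"{kind}.csv"
        with open(path, "w") as fh:
            if dialect.start_time_source == "header":
                fh.write(f"# start_time: {start_iso}\n")
                cols = sensor.columns
            else:
                cols = [dialect.time_column, *sensor.columns]
            fh.write(dialect.delimiter.join(cols) + "\n")
            times = t0 + np.arange(device_vals.shape[0]) / sensor.fs
            for i in range(device_vals.shape[0]):
                row = [f"{v:.17g}" for v in np.atleast_1d(device_vals[i])]
                if dialect.start_time_source == "column":
                    row.insert(0, f"{times[i]:.17g}")
                fh.write(dialect.delimiter.join(row) + "\n")
        paths[kind] = path
    return paths


# ---------------------------------------------------------------------------
# random stride lists for oracle sweeps
# ---------------------------------------------------------------------------


def random_stride_list(
    rng: np.random.Generator, max_strides: int = 12
) -> list[gs.StrideAnnotation]:
    """Random annotated stride list exercising the segmentation boundary cases.

    Mixes walking bursts (alternating feet, overlapping in time), pooled gaps
    drawn around the 3 s break threshold (including exactly 3.0 s), incline
    flags, and unbalanced feet.
    """
    n_target = int(rng.integers(0, max_strides + 1))
    out: list[gs.StrideAnnotation] = []
    # integer-millisecond grid: same-foot neighbours touch exactly, never overlap
    t_ms = int(rng.integers(0, 2000))
    foot = rng.choice(["left", "right"])
    while len(out) < n_target:
        burst = int(rng.integers(1, min(5, n_target - len(out)) + 1))
        half_ms = int(rng.integers(400, 701))  # half a stride cycle
        for i in range(burst):
            s_ms = t_ms + i * half_ms
            out.append(
                gs.StrideAnnotation(
                    foot=foot if i % 2 == 0 else ("right" if foot == "left" else "left"),
                    start=s_ms / 1000.0,
                    end=(s_ms + 2 * half_ms) / 1000.0,
                    on_incline=bool(rng.random() < 0.2),
                )
            )
        last_end_ms = t_ms + (burst - 1) * half_ms + 2 * half_ms
        u = rng.random()
        if u < 0.45:
            gap_ms = int(rng.integers(0, 2900))
        elif u < 0.55:
            gap_ms = 3000  # exactly at the break threshold: must NOT split
        elif u < 0.75:
            gap_ms = int(rng.integers(2900, 3101))
        else:
            gap_ms = int(rng.integers(3101, 6001))
        t_ms = last_end_ms + gap_ms
        foot = rng.choice(["left", "right"])
    return sorted(out, key=lambda s: (s.start, s.end))
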