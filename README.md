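# wearstd

Standardized hierarchical storage for wearable movement data and gait gold
standards.

Wearable inertial sensors (IMUs) are now routine instruments for measuring
mobility — walking speed, cadence, stride length — in the laboratory and in
daily life. The data they produce, however, arrive in wildly heterogeneous
shapes: every device has its own axis orientation, units, sampling rates and
file formats, and every reference ("gold standard") system — stereophotogrammetry,
instrumented walkways, pressure insoles, multi-IMU rigs — its own output. That
heterogeneity is the main obstacle to sharing, re-using and externally
validating mobility datasets.

`wearstd` implements a complete standardization procedure for such data, for
researchers who need to bring recordings from different devices and studies
into one analyzable form:

* **A validated hierarchical data model.** One subject is a folder of time
  measurements (`T1..Tn`), each with up to three recording contexts:
  `Laboratory` (structured tests with repeated trials), `Free-living`
  (one unscripted continuous recording) and `7-day` (continuous multi-day
  monitoring split into `Day1..DayN`). Each recording holds one or more
  sensor units (`SU` for the main device, `SU_<DeviceName>` for others) with
  per-location signal matrices, and optionally a `Standards` block with
  gold-standard outputs. A validator checks every structural rule and returns
  violations as data — reading never aborts.
* **Container I/O.** `data.mat` / `infoForAlgo.mat` MATLAB containers (classic
  v7 and HDF5-based v7.3), written with the exact standardized field
  vocabulary (`Acc`, `Gyr`, `Fs`, `Timestamp`, `StartDateTime`, `TimeZone`,
  `MicroWB`, …) and read back bit-faithfully — NaN samples, optional sensors
  and unknown fields included. Writes are byte-deterministic.
* **Conventions.** Tri-axial signals are stored as N×3 matrices with columns
  ordered **V** (vertical), **ML** (medio-lateral), **AP** (antero-posterior);
  a device frame is mapped into this convention by a signed permutation with
  determinant +1 (no rotation — mounting misalignment is deliberately left
  untouched at storage time). Units are normalized to g, deg/s, µT, hPa and
  °C. Location names (`LowerBack`, `LeftLowerShank`, …) live in an extensible
  UpperCamelCase registry.
* **Timing.** Per-sample Unix timestamps; IANA time zones; ISO-8601 start
  times with millisecond precision where a zero UTC offset is written as a
  trailing `Z`; timestamp reconstruction from start time and rate; and
  timezone-aware splitting of multi-day recordings at local midnight with
  half-open `[midnight, midnight)` boundaries (daylight-saving days are 23 or
  25 wall-clock hours and handled exactly).
* **Gold-standard walking sequences.** From stride-level annotations the
  package builds the three standardized walking-sequence structures:

  - **MicroWB** — a walking bout with no incline walking, no break (absence
    of stepping, pooled over both feet) strictly longer than 3 s, and at
    least 2 left and 2 right strides;
  - **ContinuousWalkingPeriod (CWP)** — the inclusive counterpart, cut only
    at breaks > 3 s, retaining incline strides and spurious bouts; every
    MicroWB lies inside exactly one CWP;
  - **Pass** — for instrumented walkways only: one sequence per maximal run
    of strides fully inside the mat's sensorized extent.

  Each sequence carries a parameter set (duration, cadence at two steps per
  stride, length, per-stride durations/speeds, stance/swing, gait-event
  lists), plus the per-sample occlusion `Flag` and `GapsPercentage` =
  100 · occluded/total.
* **A synthetic-data module** that generates complete seeded fixtures — 
  walking-like signals, stride annotations with controllable break/incline/
  spurious structure, occlusion flags, raw per-device CSV exports and full
  multi-day subject folders — together with exact ground truth computed by an
  independent brute-force segmentation oracle.
* **A CLI** (`wearstd convert / validate / split-days / inspect`) for running
  the pipeline from a shell.

## Worked example

```python
from wearstd import (FixtureSpec, generate_subject, write_subject,
                     read_subject, validate, build_micro_wbs, build_cwps)

spec = FixtureSpec(seed=42)                  # scripted free-living fixture
dataset, truth = generate_subject(spec)
write_subject(dataset, "standardized")       # standardized/1001/Free-living/data.mat

back = read_subject("standardized/1001")
print("violations:", validate(back, strict=True))

block = back.time_measurements["T1"].free_living.recording.standards.systems["Stereophoto"]
strides = [s for cwp in block.sequences["ContinuousWalkingPeriod"] for s in cwp.strides]
for wb in build_micro_wbs(strides):
    p = wb.params
    print(f"MicroWB {p.start:6.2f}-{p.end:6.2f} s  "
          f"strides {p.n_strides_left}L/{p.n_strides_right}R  "
          f"cadence {p.cadence:5.1f} steps/min  length {p.length:.2f} m")
print(f"CWPs: {len(build_cwps(strides))},  GapsPercentage: {block.gaps_percentage:.1f}")
```

prints

```
violations: []
MicroWB  10.00- 15.50 s  strides 5L/5R  cadence 218.2 steps/min  length 12.50 m
MicroWB  30.00- 33.00 s  strides 3L/2R  cadence 200.0 steps/min  length 6.25 m
MicroWB  33.50- 36.50 s  strides 2L/3R  cadence 200.0 steps/min  length 6.25 m
CWPs: 3,  GapsPercentage: 2.0
```

The default fixture scripts three bouts: a clean 10-stride bout (the first
MicroWB), a 2-stride bout that is spurious (dropped from the MicroWBs but
kept as its own CWP), and a 12-stride bout whose two middle strides climb an
incline — excising them splits the bout into the last two MicroWBs, while the
CWP keeps all 12 strides. `GapsPercentage` reflects the fixture's 2 %
marker-occlusion rate. The same folder can be inspected from the shell:

```bash
$ wearstd inspect standardized/1001
subject 1001
  T1
    Free-living
      SU.LowerBack: 4650 samples, signals ['Acc', 'Bar', 'Gyr', 'Mag', 'Temp'], start 2023-05-15T09:30:00.000+02:00 (Europe/Berlin)
      Standards.Stereophoto: {'MicroWB': 3, 'ContinuousWalkingPeriod': 3}, GapsPercentage 2.0
```

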