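# Methods

This note documents the data model, the conventions and numerical choices
behind `wearstd`, what the synthetic fixtures do and do not emulate, and the
design decisions taken where the procedure left room for choice.

## The data model

One *subject* is a folder of *time measurements* `T1..Tn` (baseline,
follow-ups). Explicit `T` directories are written only when a dataset has
more than one time measurement; a single-measurement subject keeps its
recording folders directly under the subject directory and reads back as
`T1`. Each time measurement holds up to three recording contexts:

* **Laboratory** — a structured protocol: ordered tests, each with one or
  more trials (repetitions). Nodes carry ordinal keys (`Test1`,
  `Recording1`); human-readable names are stored in a separate `Names`
  struct so that keys remain valid field names in any container.
* **Free-living** — one continuous unscripted recording.
* **7-day** — continuous multi-day monitoring, stored one local calendar day
  per `DayN` folder.

A *recording* is a set of sensor units — `SU` for the main device,
`SU_<DeviceName>` for each further device type; several same-type devices
(e.g. four IMUs of one multi-sensor reference system) are locations *within*
one unit. A location holds signal matrices (`Acc` N×3, `Gyr` N×3, `Mag` N×3,
`Bar` M×1, `Temp` K×1, optional `Quat` N×4), a per-signal sampling-frequency
struct `Fs`, and the four timing references (below). `infoForAlgo.mat`
carries algorithm metadata (sensor type, attachment `body-worn` /
`body-attached`, anthropometrics, walking-aid use) plus an open key-value
map: unknown keys round-trip untouched.

Validation is a separate pass over a loaded dataset and returns violations
as data (path, rule id, message); malformed legacy data can always be read
and inspected. Non-strict mode — intended for pre-existing datasets carrying
their original IDs and sensor placements — relaxes exactly two rules: the
four-digit `snnn` subject-ID pattern and the location registry.

## Conventions

**Axes.** Standardized tri-axial signals are column-ordered V, ML, AP. A
device frame is mapped into this frame by a *signed permutation* only; the
map must have determinant +1 because both frames are right-handed and a
reflection would silently negate every gyroscope rotation sign. No rotation
or gravity-based re-alignment is applied at storage time — small mounting
misalignment is information, and correcting it is an analysis step, not a
storage step. The positive ML direction is taken toward the subject's right,
which keeps (V up, ML right, AP forward) right-handed; flipping this
convention is a one-line change in the axis map.

**Units.** Accelerometer g (via standard gravity 9.80665 m/s², exact),
gyroscope deg/s, magnetometer µT, barometer hPa, temperature °C. All
conversions are affine (`target = a·source + b`); only temperature has a
non-zero offset. Conversions are exactly invertible up to one floating-point
rounding.

**Locations.** A registry seeded with the consortium and pre-existing-dataset
locations (`LowerBack`, `LowerBack2`, `LeftFoot`, …). New names may be
registered if they are single UpperCamelCase strings (trailing digits
allowed, as in `LowerBack2`).

## Timing

Timestamps are Unix seconds (UTC, leap seconds ignored, fractional values
allowed). `TimeZone` is an IANA identifier; `StartDateTime` is the first
sample rendered in that zone as `YYYY-MM-DDThh:mm:ss.SSS±hh:mm`, with the
offset replaced by `Z` when it is exactly zero at that instant. Rendering
rounds to the millisecond *before* formatting so a time like 23:59:59.9996
cannot produce an un-rolled date. When a stream has no stored timestamp
vector it is reconstructed as `t[k] = unix(start) + k/fs`; the temperature
sensor keeps its own timeline through `StartDateTime_Temp` and its own rate.

**Day splitting** cuts a recording at local midnights. Intervals are
half-open `[midnight, next midnight)`; a sample landing exactly on midnight
opens the new day (the procedure's "midnight to midnight" phrasing does not
decide the boundary instant, and half-open intervals are the only choice
that partitions without duplication). Each signal is cut at its *own* sample
index computed from its own timestamps or rate, so concatenating the
segments reproduces every array exactly. Ambiguous wall-clock times during
fall-back never arise because the authoritative instant is always UTC;
spring-forward days span 23 and fall-back days 25 wall-clock hours while
sample counts follow elapsed UTC time. The `Standards` block is not carried
into day segments (multi-day real-world recordings have no laboratory gold
standards attached); day splitting is a signal-level operation.

## Gold-standard walking sequences

Inputs are stride-level annotations from a reference system: foot side,
initial-contact time (`start`), next ipsilateral initial contact (`end`),
optional final contact and stride length, and incline membership. Detection
of these events is upstream of this package.

* A **break** is the pooled gap `next.start − prev.end` over the
  time-ordered stride list of *both* feet — a break is the absence of any
  stepping, not per-foot silence.
* **MicroWB**: split at breaks strictly greater than 3.0 s (a break of
  exactly 3 s does not split — "longer than 3 seconds" is read strictly, and
  the complementary phrasing "not longer than three seconds" for CWP content
  corroborates the closed boundary); excise incline strides, splitting the
  candidate at each excision; discard candidates with fewer than 2 strides
  on either foot (spurious bouts).
* **CWP**: split at breaks > 3.0 s only; incline strides and spurious groups
  are retained. Every MicroWB is contained in exactly one CWP, and raising
  the break threshold can only merge, never multiply, CWPs.
* **Pass** (instrumented walkway only): maximal runs of strides whose
  `[start, end]` lies fully inside the mat's sensorized interval.

Parameters: `duration = end − start`; `cadence = 60 · 2 · n_strides /
duration` (two steps per stride); `length` is the sum of stride lengths and
is absent unless every stride carries one; stance/swing come from the final
contact. `GapsPercentage = 100 · occluded / total` over the whole
acquisition. Which sequence kinds a system exposes is fixed
(stereophotogrammetry and the multi-IMU reference expose MicroWB + CWP, the
shank-IMU algorithm CWP only, the walkway Pass only) and enforced by the
validator. Turn and incline *intervals* are stored as annotations
(start, end, duration, angle/elevation); their detection is out of scope.

An independent **brute-force oracle** (`wearstd._oracle`) re-derives the
segmentation by enumerating every contiguous interval of the stride list,
applying the three rules literally to each, and keeping maximal admissible
intervals. It is quadratic and only usable on short lists, which is its job:
the scan-based production builders are tested against it on thousands of
randomized inputs, including gaps placed exactly at 3.0 s.

## Containers

Classic MAT v7 files are written through `scipy.io` (compressed, column
vectors, long field names); the free-text header is rewritten to a fixed
string after writing so that identical datasets produce byte-identical
files. MAT v7.3 files are written by a small HDF5 layer built on `h5py`
implementing the MATLAB HDF5 schema for the needed subset — double arrays
(transposed dims), UTF-16 char vectors, logicals, scalar structs, and 1×N
struct arrays as object-reference datasets under `/#refs#` — with a 512-byte
userblock carrying the version word, and HDF5 object-time tracking disabled
for determinism. Both versions are read back through one shared tree
decoder; readers auto-detect the version. v7.3 exists because day-long
100 Hz arrays can exceed classic-v7 variable limits.

Walking sequences are serialized with explicit per-stride fields
(`Stride_Start`, `Stride_End`, `Stride_FinalContact`, `Stride_Length`,
`Stride_Foot`, `Stride_OnIncline`) alongside the derived summary parameters;
on read, parameters are recomputed from the strides, which makes the
round trip exact and the stored summaries redundant-by-construction for
consumers that want them.

Raw device exports are ingested through a declarative *device dialect*
(YAML/JSON): per-sensor column labels, source units and rates, a shared axis
map per location, the time zone, and whether the start time comes from a
header line or a timestamp column. Supporting a new device is a config file,
not code.

## The synthetic generator

Fixtures emulate the three study settings (laboratory tests/trials,
free-living, multi-day monitoring) with a scripted bout structure. Default
conditions: 100 Hz accelerometer/gyroscope/magnetometer, 25 Hz barometer,
1 Hz temperature — typical rates for the device class — in `Europe/Berlin`;
stride time 1.0 s with contralateral contacts half a cycle apart; stride
length 1.25 m; a 2 % marker-occlusion rate, applied as exactly
`round(rate·N)` flagged samples at seeded random positions. The default
free-living script contains one clean bout, one spurious 2-stride bout
beyond a >3 s break, and one bout with two incline strides, so all three
MicroWB exclusion rules are exercised by construction.

Signals are sums of per-stride sinusoid templates plus seeded Gaussian
noise, with the 1 g gravity offset on the vertical accelerometer channel.
This is deliberate minimalism: the standard governs *storage*, so fixtures
must be exactly right about structure, timing, units and axes — which they
are by construction — while nothing about biomechanical realism (impact
transients, turning dynamics, sensor drift, soft-tissue artifact) is
claimed. Passing tests therefore demonstrate fidelity of storage,
conversion, timing and segmentation, not the behavior of any gait-detection
algorithm on real signals; detection algorithms are outside the package.

All randomness flows from one `numpy.random.Generator` seeded by the
fixture spec; there is no global random state, and equal seeds give
byte-identical folders.

## Problem sizes and numerical notes

The test suite and the acceptance script use desk-scale problem sizes chosen
as the package's own defaults: 1,000 random stride lists of ≤12 strides for
oracle equivalence (the oracle is quadratic; 12 strides already enumerate 78
intervals), 100 round-trip fixtures of ~10 s each across both container
versions, a 20-zone × 1970–2035 sweep for timing inverses, and a 1-hour
100 Hz recording for the storage-size comparison — the CSV-versus-binary
size ratio is duration-invariant, so nothing changes at 24 h beyond disk
traffic. Day-splitting stress cases run at 10 Hz for the same reason.

Degenerate inputs: an empty stride list yields no sequences; a zero-duration
sequence and an empty occlusion flag raise; a location without an `Acc`
matrix is a schema error; sequence kinds with zero instances are absent
fields, not empty arrays. Floating-point policy: axis remapping and
container round trips are exact; unit conversions and raw-CSV round trips
are exact to one rounding (CSV values are written with 17 significant
digits); millisecond rendering uses round-half-even on the total
millisecond count.

## Known limitations

* The v7.3 writer/reader covers the schema subset the standard needs, not
  arbitrary MATLAB files (no cells of cells, sparse, complex, or objects).
* Contextual folders (weather, indoor position) are detected and preserved,
  never parsed; clinical metadata is out of scope.
* Cross-device clock-drift correction and hardware synchronization are out
  of scope; alignment relies on shared timestamps only.
* The full consortium parameter taxonomy for walking sequences and the full
  `infoForAlgo` field list are not public; a documented core subset is
  implemented and unknown fields round-trip untouched.
* Turn/incline detection and all mobility-outcome estimation algorithms are
  explicitly not part of the package.
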