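"""Gold-standard walking sequences: MicroWB, ContinuousWalkingPeriod, Pass.

Reference systems (stereophotogrammetry, a multi-IMU + pressure-insole system,
an instrumented walkway, a shank-IMU algorithm) deliver stride-level gait
annotations.  This module turns those annotations into the standardized
walking-sequence structures and their parameter sets:

* A **MicroWB** is a walking bout containing no incline walking, no break
  (absence of any stepping, pooled across both feet) longer than 3 seconds,
  and at least 2 left and 2 right strides.  "Longer than" is strict — a break
  of exactly 3.0 s does not split.
* A **ContinuousWalkingPeriod** (CWP) is the inclusive counterpart: it is cut
  only at breaks longer than 3 seconds and keeps incline strides and spurious
  bouts (those with fewer than 2 strides on either side).  Every MicroWB is
  contained in exactly one CWP.
* A **Pass** exists only for the instrumented walkway: one sequence per
  maximal run of strides fully inside the mat's sensorized interval.

Detection of gait events, turns and inclines happens upstream in the reference
systems; here they are data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrideAnnotation",
    "WalkingSequence",
    "ParameterSet",
    "GoldStandardBlock",
    "Standards",
    "AnnotationError",
    "BREAK_THRESHOLD_S",
    "MIN_STRIDES_PER_SIDE",
    "SEQUENCE_KINDS",
    "SYSTEM_SEQUENCE_KINDS",
    "build_micro_wbs",
    "build_cwps",
    "build_passes",
    "compute_parameters",
    "compute_gaps_percentage",
    "strides_to_csv",
    "strides_from_csv",
    "check_standards",
]

BREAK_THRESHOLD_S = 3.0
MIN_STRIDES_PER_SIDE = 2

SEQUENCE_KINDS = ("MicroWB", "ContinuousWalkingPeriod", "Pass")

#: Which walking-sequence kinds each reference system exposes.
SYSTEM_SEQUENCE_KINDS: dict[str, tuple[str, ...]] = {
    "Stereophoto": ("MicroWB", "ContinuousWalkingPeriod"),
    "INDIP": ("MicroWB", "ContinuousWalkingPeriod"),
    "SU_LowerShanks": ("ContinuousWalkingPeriod",),
    "Walkway": ("Pass",),
}


class AnnotationError(ValueError):
    """Inconsistent stride annotations (e.g. overlapping same-foot strides)."""


@dataclass(frozen=True)
class StrideAnnotation:
    """One gold-standard stride: ipsilateral initial contact to the next.

    ``start``/``end`` are the two initial-contact times (seconds on the
    recording timeline); ``final_contact``, when present, lies strictly
    inside the stride and separates stance from swing.
    """

    foot: str  # "left" | "right"
    start: float
    end: float
    final_contact: float | None = None
    length: float | None = None  # metres
    on_incline: bool = False
    extras: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.foot not in ("left", "right"):
            raise AnnotationError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if not self.start < self.end:
            raise AnnotationError(
                f"stride start ({self.start}) must precede end ({self.end})"
            )
        if self.final_contact is not None and not (
            self.start < self.final_contact < self.end
        ):
            raise AnnotationError(
                f"final contact {self.final_contact} must lie inside "
                f"({self.start}, {self.end})"
            )


@dataclass
class ParameterSet:
    """Summary parameters of one walking sequence.

    Cadence uses the two-steps-per-stride convention:
    ``cadence = 60 * 2 * n_strides / duration`` steps/min.
    """

    start: float
    end: float
    duration: float
    n_strides: int
    n_strides_left: int
    n_strides_right: int
    cadence: float
    length: float | None  # sum of stride lengths; absent unless all present
    stride_duration: np.ndarray
    stride_length: np.ndarray | None
    stride_speed: np.ndarray | None
    stance: np.ndarray | None
    swing: np.ndarray | None
    initial_contacts: np.ndarray
    final_contacts: np.ndarray | None
    contact_feet: list[str]


@dataclass
class WalkingSequence:
    """A MicroWB, ContinuousWalkingPeriod, or Pass with its parameters."""

    kind: str
    strides: list[StrideAnnotation]
    params: ParameterSet | None = None
    turns: list[tuple[float, float, float, float]] = field(default_factory=list)
    inclines: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in SEQUENCE_KINDS:
            raise ValueError(f"kind must be one of {SEQUENCE_KINDS}, got {self.kind!r}")
        if not self.strides:
            raise ValueError("a walking sequence must contain at least one stride")

    @property
    def start(self) -> float:
        return min(s.start for s in self.strides)

    @property
    def end(self) -> float:
        return max(s.end for s in self.strides)


@dataclass
class GoldStandardBlock:
    """One reference system's processed output inside the Standards block."""

    fs: float
    sequences: dict[str, list[WalkingSequence]] = field(default_factory=dict)
    flag: np.ndarray | None = None  # per-sample bool: occlusion / on-mat
    gaps_percentage: float | None = None
    raw: Any | None = None  # opaque <Name>_raw payload


@dataclass
class Standards:
    """All gold standards attached to one recording, keyed by system name."""

    systems: dict[str, GoldStandardBlock] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _sorted_checked(strides: Iterable[StrideAnnotation]) -> list[StrideAnnotation]:
    out = sorted(strides, key=lambda s: (s.start, s.end))
    last_end: dict[str, float] = {}
    for s in out:
        if s.foot in last_end and s.start < last_end[s.foot]:
            raise AnnotationError(
                f"overlapping {s.foot}-foot strides around t={s.start:.3f}s"
            )
        last_end[s.foot] = s.end
    return out


def _split_at_breaks(
    strides: Sequence[StrideAnnotation], threshold: float
) -> list[list[StrideAnnotation]]:
    """Partition at every pooled inter-stride gap strictly greater than threshold."""
    groups: list[list[StrideAnnotation]] = []
    cur: list[StrideAnnotation] = []
    for s in strides:
        if cur and s.start - cur[-1].end > threshold:
            groups.append(cur)
            cur = []
        cur.append(s)
    if cur:
        groups.append(cur)
    return groups


def build_cwps(
    strides: Iterable[StrideAnnotation],
    break_threshold: float = BREAK_THRESHOLD_S,
    with_params: bool = True,
) -> list[WalkingSequence]:
    """Build ContinuousWalkingPeriods: cut only at breaks > *break_threshold*.

    Incline strides and spurious groups are retained; every MicroWB produced
    from the same input is fully contained in exactly one CWP.
    """
    ordered = _sorted_checked(strides)
    return [
        _make_sequence("ContinuousWalkingPeriod", grp, with_params)
        for grp in _split_at_breaks(ordered, break_threshold)
    ]


def build_micro_wbs(
    strides: Iterable[StrideAnnotation],
    break_threshold: float = BREAK_THRESHOLD_S,
    min_strides_per_side: int = MIN_STRIDES_PER_SIDE,
    with_params: bool = True,
) -> list[WalkingSequence]:
    """Build MicroWBs by the three exclusion rules.

    1. cut at every pooled inter-stride break strictly longer than
       *break_threshold* (default 3 s);
    2. excise incline strides, splitting candidates at each excision;
    3. discard candidates with fewer than *min_strides_per_side* strides on
       either foot (spurious bouts).
    """
    ordered = _sorted_checked(strides)
    out: list[WalkingSequence] = []
    for grp in _split_at_breaks(ordered, break_threshold):
        for cand in _split_on_incline(grp):
            left = sum(1 for s in cand if s.foot == "left")
            right = len(cand) - left
            if left >= min_strides_per_side and right >= min_strides_per_side:
                out.append(_make_sequence("MicroWB", cand, with_params))
    return out


def _split_on_incline(
    group: Sequence[StrideAnnotation],
) -> list[list[StrideAnnotation]]:
    cands: list[list[StrideAnnotation]] = []
    cur: list[StrideAnnotation] = []
    for s in group:
        if s.on_incline:
            if cur:
                cands.append(cur)
                cur = []
        else:
            cur.append(s)
    if cur:
        cands.append(cur)
    return cands


def build_passes(
    strides: Iterable[StrideAnnotation],
    mat_interval: tuple[float, float],
    with_params: bool = True,
) -> list[WalkingSequence]:
    """Walkway Passes: one per maximal run of strides fully inside the mat.

    The mat's sensorized extent is a time interval on the recording timeline;
    strides straddling either edge are excluded.
    """
    lo, hi = mat_interval
    if not lo < hi:
        raise ValueError(f"mat interval must be well-ordered, got ({lo}, {hi})")
    ordered = _sorted_checked(strides)
    out: list[WalkingSequence] = []
    cur: list[StrideAnnotation] = []
    for s in ordered:
        if lo <= s.start and s.end <= hi:
            cur.append(s)
        elif cur:
            out.append(_make_sequence("Pass", cur, with_params))
            cur = []
    if cur:
        out.append(_make_sequence("Pass", cur, with_params))
    return out


def _make_sequence(
    kind: str, strides: list[StrideAnnotation], with_params: bool
) -> WalkingSequence:
    seq = WalkingSequence(kind=kind, strides=list(strides))
    if with_params:
        seq.params = compute_parameters(seq)
    return seq


# ---------------------------------------------------------------------------
# Parameters and annotations
# ---------------------------------------------------------------------------


def compute_parameters(seq: WalkingSequence) -> ParameterSet:
    """Core parameter set of a walking sequence.

    duration = end - start; length = sum of stride lengths when all strides
    carry one; cadence = 60 * steps / duration with two steps per stride;
    stance/swing from the final contact when annotated.
    """
    strides = seq.strides
    start, end = seq.start, seq.end
    duration = end - start
    if duration <= 0:
        raise ValueError(f"degenerate zero-duration sequence at t={start}")
    n = len(strides)
    lengths = [s.length for s in strides]
    length = float(np.sum(lengths)) if all(v is not None for v in lengths) else None
    stride_duration = np.array([s.end - s.start for s in strides])
    stride_length = (
        np.array([float(v) for v in lengths]) if length is not None else None
    )
    stride_speed = (
        stride_length / stride_duration if stride_length is not None else None
    )
    fcs = [s.final_contact for s in strides]
    if all(v is not None for v in fcs):
        final_contacts = np.array([float(v) for v in fcs])
        stance = final_contacts - np.array([s.start for s in strides])
        swing = np.array([s.end for s in strides]) - final_contacts
    else:
        final_contacts = stance = swing = None
    return ParameterSet(
        start=start,
        end=end,
        duration=duration,
        n_strides=n,
        n_strides_left=sum(1 for s in strides if s.foot == "left"),
        n_strides_right=sum(1 for s in strides if s.foot == "right"),
        cadence=60.0 * (2 * n) / duration,
        length=length,
        stride_duration=stride_duration,
        stride_length=stride_length,
        stride_speed=stride_speed,
        stance=stance,
        swing=swing,
        initial_contacts=np.array([s.start for s in strides]),
        final_contacts=final_contacts,
        contact_feet=[s.foot for s in strides],
    )


def compute_gaps_percentage(flag: np.ndarray) -> float:
    """Percent of samples with marker occlusion over the whole acquisition."""
    flag = np.asarray(flag)
    if flag.size == 0:
        raise ValueError("flag vector is empty")
    return 100.0 * float(np.count_nonzero(flag)) / flag.size


# ---------------------------------------------------------------------------
# CSV interchange for stride annotations
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["foot", "start", "end", "final_contact", "length", "on_incline"]


def strides_to_csv(strides: Sequence[StrideAnnotation], path) -> None:
    """Write one row per stride (the fixture interchange format)."""
    df = pd.DataFrame(
        {
            "foot": [s.foot for s in strides],
            "start": [s.start for s in strides],
            "end": [s.end for s in strides],
            "final_contact": [s.final_contact for s in strides],
            "length": [s.length for s in strides],
            "on_incline": [s.on_incline for s in strides],
        }
    )
    df.to_csv(path, index=False)


def strides_from_csv(path) -> list[StrideAnnotation]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"stride CSV {path} is missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        fc = getattr(row, "final_contact")
        ln = getattr(row, "length")
        out.append(
            StrideAnnotation(
                foot=str(row.foot),
                start=float(row.start),
                end=float(row.end),
                final_contact=None if pd.isna(fc) else float(fc),
                length=None if pd.isna(ln) else float(ln),
                on_incline=bool(row.on_incline),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Validation hook (called from wearstd.schema.validate)
# ---------------------------------------------------------------------------


def check_standards(standards: Standards, path: str, out: list) -> None:
    """Append Violations for broken Standards invariants (shared validator)."""
    from .schema import Violation

    for name, block in standards.systems.items():
        bpath = f"{path}.{name}"
        allowed = SYSTEM_SEQUENCE_KINDS.get(name)
        for kind, seqs in block.sequences.items():
            if kind not in SEQUENCE_KINDS:
                out.append(
                    Violation(
                        f"{bpath}.{kind}", "sequence-kind",
                        f"unknown walking-sequence kind {kind!r}",
                    )
                )
                continue
            if allowed is not None and kind not in allowed:
                out.append(
                    Violation(
                        f"{bpath}.{kind}", "system-sequence-kinds",
                        f"system {name!r} exposes {allowed}, not {kind!r}",
                    )
                )
            for i, seq in enumerate(seqs, start=1):
                if seq.kind != kind:
                    out.append(
                        Violation(
                            f"{bpath}.{kind}({i})", "sequence-kind",
                            f"sequence stored under {kind} has kind {seq.kind!r}",
                        )
                    )
                if kind == "MicroWB":
                    _check_micro_wb(seq, f"{bpath}.MicroWB({i})", out)
        if block.gaps_percentage is not None and not (
            0.0 <= block.gaps_percentage <= 100.0
        ):
            out.append(
                Violation(
                    f"{bpath}.Annotations.GapsPercentage", "gaps-percentage-range",
                    f"GapsPercentage must be in [0, 100], got {block.gaps_percentage}",
                )
            )


def _check_micro_wb(seq: WalkingSequence, path: str, out: list) -> None:
    from .schema import Violation

    if any(s.on_incline for s in seq.strides):
        out.append(
            Violation(path, "microwb-no-incline", "MicroWB contains incline strides")
        )
    ordered = sorted(seq.strides, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start - a.end > BREAK_THRESHOLD_S:
            out.append(
                Violation(
                    path, "microwb-break",
                    f"MicroWB contains a break of {b.start - a.end:.3f}s "
                    f"(> {BREAK_THRESHOLD_S}s)",
                )
            )
            break
    left = sum(1 for s in seq.strides if s.foot == "left")
    right = len(seq.strides) - left
    if left < MIN_STRIDES_PER_SIDE or right < MIN_STRIDES_PER_SIDE:
        out.append(
            Violation(
                path, "microwb-spurious",
                f"MicroWB needs >=2 strides per foot, got {left} left / {right} right",
            )
        )
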