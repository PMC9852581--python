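"""Exhaustive reference segmentation by interval enumeration.

An independent cross-check for the scan-based builders in
:mod:`wearstd.goldstd`: instead of scanning, it enumerates *every* contiguous
interval of the time-ordered stride list, tests the bout rules literally on
each interval, and keeps the maximal admissible ones.  Quadratic in the number
of strides, so only usable on small inputs — which is the point: it is the
brute-force ground truth the synthetic generator and the test suite compare
the production code against.
"""

from __future__ import annotations

from typing import Sequence

from .goldstd import (
    BREAK_THRESHOLD_S,
    MIN_STRIDES_PER_SIDE,
    StrideAnnotation,
)

__all__ = ["oracle_cwp_intervals", "oracle_micro_wb_intervals", "intervals_of"]


def _ordered(strides: Sequence[StrideAnnotation]) -> list[StrideAnnotation]:
    return sorted(strides, key=lambda s: (s.start, s.end))


def _gaps_ok(chunk: Sequence[StrideAnnotation], threshold: float) -> bool:
    return all(
        b.start - a.end <= threshold for a, b in zip(chunk, chunk[1:])
    )


def oracle_cwp_intervals(
    strides: Sequence[StrideAnnotation], threshold: float = BREAK_THRESHOLD_S
) -> list[list[StrideAnnotation]]:
    """All maximal contiguous intervals whose internal breaks are <= threshold."""
    s = _ordered(strides)
    n = len(s)
    valid = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n + 1)
        if _gaps_ok(s[i:j], threshold)
    ]
    maximal = [
        (i, j)
        for (i, j) in valid
        if not any((p <= i and j <= q and (p, q) != (i, j)) for (p, q) in valid)
    ]
    return [s[i:j] for i, j in sorted(maximal)]


def oracle_micro_wb_intervals(
    strides: Sequence[StrideAnnotation],
    threshold: float = BREAK_THRESHOLD_S,
    min_per_side: int = MIN_STRIDES_PER_SIDE,
) -> list[list[StrideAnnotation]]:
    """Maximal level-walking intervals, then the spurious-bout filter.

    An interval is admissible when it contains no incline stride and no
    internal break longer than *threshold*, and it must not be extendable —
    the stride immediately before/after must be absent, on an incline, or
    beyond a break.  Of the maximal intervals, only those with at least
    *min_per_side* strides of each foot survive.
    """
    s = _ordered(strides)
    n = len(s)
    valid = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n + 1)
        if not any(x.on_incline for x in s[i:j]) and _gaps_ok(s[i:j], threshold)
    ]
    maximal = [
        (i, j)
        for (i, j) in valid
        if not any((p <= i and j <= q and (p, q) != (i, j)) for (p, q) in valid)
    ]
    out = []
    for i, j in sorted(maximal):
        chunk = s[i:j]
        left = sum(1 for x in chunk if x.foot == "left")
        if left >= min_per_side and len(chunk) - left >= min_per_side:
            out.append(chunk)
    return out


def intervals_of(sequences) -> list[tuple[float, ...]]:
    """Hashable fingerprint of a segmentation for equality comparisons."""
    out = []
    for chunk in sequences:
        strides = getattr(chunk, "strides", chunk)
        out.append(tuple(round(s.start, 9) for s in strides))
    return out
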