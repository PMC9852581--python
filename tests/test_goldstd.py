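"""Walking-bout construction rules, parameters, and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearstd import goldstd as gs
from wearstd._oracle import (
    intervals_of,
    oracle_cwp_intervals,
    oracle_micro_wb_intervals,
)
from wearstd.synthetic import random_stride_list


def _walk(n, start=0.0, d=1.0, first="left", incline=()):
    """n alternating-foot strides, contralateral contacts half a cycle apart."""
    feet = ("left", "right") if first == "left" else ("right", "left")
    return [
        gs.StrideAnnotation(
            foot=feet[i % 2],
            start=start + i * d / 2,
            end=start + i * d / 2 + d,
            length=1.2,
            final_contact=start + i * d / 2 + 0.6 * d,
            on_incline=i in incline,
        )
        for i in range(n)
    ]


def test_empty_input_yields_no_bouts():
    assert gs.build_micro_wbs([]) == []
    assert gs.build_cwps([]) == []


def test_contiguous_balanced_walk_is_one_micro_wb():
    strides = _walk(4)
    out = gs.build_micro_wbs(strides)
    assert len(out) == 1 and len(out[0].strides) == 4


def test_two_spurious_groups_yield_no_micro_wb_but_two_cwps():
    first = _walk(2)
    second = _walk(2, start=first[-1].end + 3.5)
    strides = first + second
    assert gs.build_micro_wbs(strides) == []
    cwps = gs.build_cwps(strides)
    assert [len(c.strides) for c in cwps] == [2, 2]


def test_break_of_exactly_three_seconds_does_not_split():
    first = _walk(4)
    second = _walk(4, start=first[-1].end + 3.0)
    assert len(gs.build_micro_wbs(first + second)) == 1
    assert len(gs.build_cwps(first + second)) == 1
    third = _walk(4, start=first[-1].end + 3.0 + 1e-9)
    assert len(gs.build_cwps(first + third)) == 2


def test_incline_strides_split_micro_wbs_but_not_cwps():
    strides = _walk(10, incline=(4, 5))
    mwbs = gs.build_micro_wbs(strides)
    cwps = gs.build_cwps(strides)
    assert [len(m.strides) for m in mwbs] == [4, 4]
    assert all(not s.on_incline for m in mwbs for s in m.strides)
    assert len(cwps) == 1 and len(cwps[0].strides) == 10


def test_unbalanced_feet_disqualify_micro_wb():
    strides = [
        gs.StrideAnnotation("left", i, i + 1.0) for i in np.arange(0.0, 4.0)
    ] + [gs.StrideAnnotation("right", 4.0, 5.0)]
    assert gs.build_micro_wbs(strides) == []  # 4 left / 1 right
    assert len(gs.build_cwps(strides)) == 1


def test_overlapping_same_foot_strides_are_an_annotation_error():
    strides = [
        gs.StrideAnnotation("left", 0.0, 1.2),
        gs.StrideAnnotation("left", 1.0, 2.2),
    ]
    with pytest.raises(gs.AnnotationError):
        gs.build_micro_wbs(strides)


def test_passes_bounded_by_mat_interval():
    strides = _walk(8)
    full = gs.build_passes(strides, (-1.0, 100.0))
    assert len(full) == 1 and len(full[0].strides) == 8
    # mat covers only the middle: straddling strides excluded
    clipped = gs.build_passes(strides, (strides[2].start, strides[5].end))
    assert len(clipped) == 1
    assert all(
        strides[2].start <= s.start and s.end <= strides[5].end
        for s in clipped[0].strides
    )
    assert gs.build_passes(strides, (90.0, 100.0)) == []


def test_parameters_of_contiguous_walk():
    # 4 strides, 1.0 s and 1.2 m each, contralateral offsets: span 2.5 s
    strides = _walk(4, d=1.0)
    seq = gs.WalkingSequence("MicroWB", strides)
    p = gs.compute_parameters(seq)
    assert p.duration == pytest.approx(2.5)
    assert p.length == pytest.approx(4.8)
    assert p.cadence == pytest.approx(60.0 * 8 / 2.5)
    np.testing.assert_allclose(p.stride_duration, 1.0)
    np.testing.assert_allclose(p.stride_speed, 1.2)


def test_parameters_of_single_stride_pass():
    seq = gs.WalkingSequence(
        "Pass", [gs.StrideAnnotation("left", 0.0, 1.0, final_contact=0.6, length=1.3)]
    )
    p = gs.compute_parameters(seq)
    assert p.cadence == pytest.approx(120.0)
    assert p.length == pytest.approx(1.3)
    np.testing.assert_allclose(p.stance, [0.6])
    np.testing.assert_allclose(p.swing, [0.4])


def test_length_absent_unless_every_stride_has_one():
    strides = _walk(4)
    strides[2] = gs.StrideAnnotation(
        strides[2].foot, strides[2].start, strides[2].end, length=None
    )
    p = gs.compute_parameters(gs.WalkingSequence("ContinuousWalkingPeriod", strides))
    assert p.length is None and p.stride_length is None


@pytest.mark.parametrize(
    "flag,expected",
    [([0, 0, 1, 0, 1, 0, 0, 0, 0, 0], 20.0), (np.zeros(50), 0.0), (np.ones(7), 100.0)],
)
def test_gaps_percentage(flag, expected):
    assert gs.compute_gaps_percentage(np.asarray(flag, dtype=bool)) == expected


def test_gaps_percentage_rejects_empty():
    with pytest.raises(ValueError):
        gs.compute_gaps_percentage(np.zeros(0, dtype=bool))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.permutations(list(range(40))))
def test_gaps_percentage_invariant_under_permutation(perm):
    base = np.arange(40) % 5 == 0
    assert gs.compute_gaps_percentage(base[perm]) == gs.compute_gaps_percentage(base)


def test_gaps_percentage_concatenation_is_weighted_mean(rng):
    a = rng.random(30) < 0.3
    b = rng.random(70) < 0.1
    whole = gs.compute_gaps_percentage(np.concatenate([a, b]))
    weighted = 0.3 * gs.compute_gaps_percentage(a) + 0.7 * gs.compute_gaps_percentage(b)
    assert whole == pytest.approx(weighted)


def test_scan_builders_match_exhaustive_oracle(rng):
    """Scan-based builders agree with interval enumeration on random inputs."""
    for _ in range(400):
        strides = random_stride_list(rng)
        assert intervals_of(gs.build_micro_wbs(strides, with_params=False)) == (
            intervals_of(oracle_micro_wb_intervals(strides))
        )
        assert intervals_of(gs.build_cwps(strides, with_params=False)) == (
            intervals_of(oracle_cwp_intervals(strides))
        )


def test_every_micro_wb_nests_in_exactly_one_cwp(rng):
    for _ in range(200):
        strides = random_stride_list(rng)
        cwps = gs.build_cwps(strides, with_params=False)
        for mwb in gs.build_micro_wbs(strides, with_params=False):
            hosts = [
                c for c in cwps if c.start <= mwb.start and mwb.end <= c.end
            ]
            assert len(hosts) == 1


def test_raising_break_threshold_never_increases_cwp_count(rng):
    for _ in range(100):
        strides = random_stride_list(rng)
        counts = [
            len(gs.build_cwps(strides, break_threshold=th, with_params=False))
            for th in (0.5, 1.5, 3.0, 4.5, 6.5)
        ]
        assert counts == sorted(counts, reverse=True)


def test_stride_csv_round_trip(tmp_path):
    strides = _walk(6, incline=(2,))
    path = tmp_path / "strides.csv"
    gs.strides_to_csv(strides, path)
    back = gs.strides_from_csv(path)
    assert back == strides
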