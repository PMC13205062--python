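"""Three-level fatigue labeling: mapping, segmentation, refinement rules."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatigue3.config import WindowConfig
from fatigue3.labeling import (
    BehaviorSeries,
    TransitionSegment,
    assign_windows,
    build_timeline,
    compute_perclos,
    detect_valid_yawns,
    fisa_to_levels,
    refine_transitions,
    segment_intervals,
)
from fatigue3.types import Interval, StageTimeline


@pytest.mark.parametrize(
    "score,level",
    [(1, "NonF"), (2, "NonF"), (3, "ModF"), (4, "SevF"), (5, "SevF")],
)
def test_fisa_score_mapping(score, level):
    assert fisa_to_levels([(10.0, score)]) == [(10.0, level)]


def test_fisa_rejects_bad_scores_and_times():
    with pytest.raises(ValueError):
        fisa_to_levels([(10.0, 0)])
    with pytest.raises(ValueError):
        fisa_to_levels([(10.0, 6)])
    with pytest.raises(ValueError):
        fisa_to_levels([(10.0, 2), (10.0, 3)])


def test_segment_intervals_constant_and_transitions():
    const, segs = segment_intervals([(10.0, "NonF"), (20.0, "NonF")])
    assert const == [(10.0, 20.0, "NonF")] and segs == []

    _, segs = segment_intervals([(20.0, "NonF"), (30.0, "ModF")])
    assert len(segs) == 1 and segs[0].n_steps == 1 and segs[0].direction == "up"

    # a two-level jump inside one inter-report interval
    _, segs = segment_intervals([(30.0, "NonF"), (40.0, "SevF")])
    assert segs[0].n_steps == 2

    _, segs = segment_intervals([(30.0, "SevF"), (40.0, "NonF")])
    assert segs[0].n_steps == 2 and segs[0].direction == "down"

    with pytest.raises(ValueError):
        segment_intervals([(10.0, "NonF")])


def test_perclos_block_fractions():
    # 2 s closed of an 8 s block at 1 Hz
    eye = np.array([1, 1, 0, 0, 0, 0, 0, 0], float)
    vals, times = compute_perclos(eye, rate_hz=1.0)
    assert vals == pytest.approx([0.25]) and times[0] == 0.0

    assert compute_perclos(np.zeros(16), 1.0)[0] == pytest.approx([0.0, 0.0])
    assert compute_perclos(np.ones(16), 1.0)[0] == pytest.approx([1.0, 1.0])
    assert compute_perclos(np.tile([0, 1], 8), 1.0)[0] == pytest.approx([0.5, 0.5])

    # trailing partial block dropped
    vals, _ = compute_perclos(np.ones(19), 1.0)
    assert len(vals) == 2

    with pytest.raises(ValueError):
        compute_perclos(np.array([]), 1.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 1), min_size=8, max_size=200))
def test_perclos_values_bounded(bits):
    vals, _ = compute_perclos(np.array(bits, float), rate_hz=1.0)
    assert np.all((vals >= 0) & (vals <= 1))


def test_yawn_validity_is_strict():
    events = [(10.0, 1.5), (5.0, 1.6), (20.0, 0.0), (1.0, 3.0)]
    valid = detect_valid_yawns(events)
    assert valid == [(1.0, 3.0), (5.0, 1.6)]  # 1.5 s excluded, sorted
    assert detect_valid_yawns([]) == []


def _behavior(perclos, t0=0.0, yawns=()):
    vals = np.asarray(perclos, float)
    times = t0 + 8.0 * np.arange(vals.size)
    return BehaviorSeries(vals, times, list(yawns))


def test_refine_upward_from_perclos_step():
    # step 0.02 -> 0.20 mid-segment; derivative argmax marks the step block
    seg = TransitionSegment(1200.0, 1800.0, "NonF", "ModF")
    vals = np.full(80, 0.02)
    vals[60:] = 0.20
    b = _behavior(vals, t0=1000.0)
    t_step = 1000.0 + 60 * 8.0
    pts = refine_transitions(seg, b)
    assert len(pts) == 1
    assert pts[0].time_s == pytest.approx(t_step)
    assert pts[0].evidence == "perclos_derivative"


def test_refine_upward_earliest_candidate_wins():
    # yawn at 33 min beats a later derivative spike at 35 min
    seg = TransitionSegment(30 * 60.0, 40 * 60.0, "NonF", "ModF")
    vals = np.full(200, 0.02)
    idx_spike = int(35 * 60 / 8)
    vals[idx_spike:] = 0.3
    b = _behavior(vals, yawns=[(33 * 60.0, 2.0)])
    pts = refine_transitions(seg, b)
    assert pts[0].time_s == pytest.approx(33 * 60.0)
    assert pts[0].evidence == "yawn"


def test_refine_downward_uses_derivative_only():
    seg = TransitionSegment(30 * 60.0, 40 * 60.0, "SevF", "ModF")
    vals = np.full(300, 0.3)
    idx = int(34 * 60 / 8)
    vals[idx:] = 0.05
    # the yawn would be earlier, but yawns do not witness recovery
    b = _behavior(vals, yawns=[(31 * 60.0, 2.0)])
    pts = refine_transitions(seg, b)
    assert len(pts) == 1
    assert pts[0].direction == "down"
    assert pts[0].evidence == "perclos_derivative"
    assert abs(pts[0].time_s - 34 * 60.0) <= 8.0


def test_refine_fallback_flags_low_confidence():
    seg = TransitionSegment(600.0, 1200.0, "NonF", "ModF")
    b = BehaviorSeries(np.array([0.02]), np.array([650.0]), [])
    pts = refine_transitions(seg, b)
    assert len(pts) == 1 and pts[0].low_confidence
    assert pts[0].time_s == pytest.approx(900.0)


def test_build_timeline_single_stage():
    b = _behavior(np.full(700, 0.02))
    reports = [(11.0, 2), (21.0, 1), (31.0, 2), (41.0, 2), (51.0, 1), (61.0, 2), (71.0, 1), (81.0, 2)]
    tl = build_timeline(reports, b)
    assert len(tl.intervals) == 1
    assert tl.intervals[0].label == "NonF"
    assert (tl.intervals[0].start_s, tl.intervals[0].end_s) == (60.0, 4860.0)


def test_build_timeline_double_step_creates_middle_stage():
    # NonF@40 -> SevF@50 with one yawn and one derivative spike
    vals = np.full(700, 0.02)
    vals[int(44 * 60 / 8):] = 0.25  # largest derivative at 44 min
    vals[int(46 * 60 / 8):] = 0.32  # second-largest at 46 min
    b = _behavior(vals, yawns=[(42 * 60.0, 2.0)])
    reports = [(11.0, 1), (21.0, 1), (31.0, 1), (41.0, 1), (51.0, 5), (61.0, 5), (71.0, 5), (81.0, 5)]
    tl = build_timeline(reports, b)
    labels = [i.label for i in tl.intervals]
    assert labels == ["NonF", "ModF", "SevF"]
    assert len(tl.transitions) == 2
    assert tl.transitions[0].time_s == pytest.approx(42 * 60.0)


def test_assign_windows_midpoint_rule():
    tl = StageTimeline(
        [Interval(60.0, 105.0, "NonF"), Interval(105.0, 4860.0, "ModF")]
    )
    labels = assign_windows(tl)
    assert len(labels) == 160
    assert labels[0] == (75.0, "NonF")
    # midpoint exactly at the transition -> later stage
    assert labels[1] == (105.0, "ModF")


def test_short_stage_keeps_multiple_windows():
    # a 112 s stage aligned to the window grid holds >= 3 midpoints
    tl = StageTimeline(
        [
            Interval(60.0, 1200.0, "NonF"),
            Interval(1200.0, 1312.0, "ModF"),
            Interval(1312.0, 4860.0, "SevF"),
        ]
    )
    labels = assign_windows(tl)
    n_modf = sum(1 for _, s in labels if s == "ModF")
    assert n_modf >= 3


def test_timeline_validation_rejects_gaps_and_repeats():
    with pytest.raises(ValueError):
        StageTimeline([Interval(60.0, 100.0, "NonF"), Interval(110.0, 4860.0, "ModF")]).validate(60.0, 4860.0)
    with pytest.raises(ValueError):
        StageTimeline([Interval(60.0, 100.0, "NonF"), Interval(100.0, 4860.0, "NonF")]).validate(60.0, 4860.0)
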