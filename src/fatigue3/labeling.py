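"""Three-level fatigue labeling.

Coarse segmentation comes from the 1-5 verbal self-assessment reported every
10 minutes (1-2 -> NonF, 3 -> ModF, 4-5 -> SevF).  Inside each inter-report
interval where the level changes ("transition segment"), the transition time
is refined from facial behavior: upward transitions from the largest PERCLOS
first differences and the earliest valid yawns, downward transitions from the
most negative PERCLOS first differences only (yawning accompanies fatigue
accumulation, not recovery).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import STAGE_INDEX, STAGES, WindowConfig
from .types import Interval, StageTimeline, TransitionPoint

PERCLOS_PERIOD_S = 8.0
YAWN_MIN_DURATION_S = 1.5

_LEVEL_FROM_SCORE = {1: "NonF", 2: "NonF", 3: "ModF", 4: "SevF", 5: "SevF"}
_LEVEL_NAME = {v: k for k, v in STAGE_INDEX.items()}


@dataclass
class TransitionSegment:
    """One inter-report interval whose start and end fatigue levels differ."""

    t_start_s: float
    t_end_s: float
    level_start: str
    level_end: str

    @property
    def n_steps(self) -> int:
        return abs(STAGE_INDEX[self.level_end] - STAGE_INDEX[self.level_start])

    @property
    def direction(self) -> str:
        return "up" if STAGE_INDEX[self.level_end] > STAGE_INDEX[self.level_start] else "down"


@dataclass
class BehaviorSeries:
    """PERCLOS values every 8 s plus validated yawn events."""

    perclos: np.ndarray
    perclos_times_s: np.ndarray  # block start times
    yawns: list[tuple[float, float]]  # (start_s, duration_s), valid only


def fisa_to_levels(reports: list[tuple[float, int]]) -> list[tuple[float, str]]:
    """Map (time_min, score) self-reports to (time_min, stage-level) pairs."""
    out: list[tuple[float, str]] = []
    prev = -np.inf
    for t, score in reports:
        if score not in _LEVEL_FROM_SCORE:
            raise ValueError(f"F-ISA score {score} outside 1..5")
        if t <= prev:
            raise ValueError("F-ISA report times must be strictly increasing")
        prev = t
        out.append((t, _LEVEL_FROM_SCORE[score]))
    return out


def segment_intervals(
    levels: list[tuple[float, str]],
) -> tuple[list[tuple[float, float, str]], list[TransitionSegment]]:
    """Split inter-report intervals into constant intervals and transition segments.

    Times are minutes, as reported; constant intervals are returned as
    (start_min, end_min, level).
    """
    if len(levels) < 2:
        raise ValueError("need at least two reports")
    constant: list[tuple[float, float, str]] = []
    segments: list[TransitionSegment] = []
    for (t0, l0), (t1, l1) in zip(levels, levels[1:]):
        if l0 == l1:
            constant.append((t0, t1, l0))
        else:
            segments.append(
                TransitionSegment(t0 * 60.0, t1 * 60.0, l0, l1)
            )
    return constant, segments


def compute_perclos(
    eye_state: np.ndarray, rate_hz: float, period_s: float = PERCLOS_PERIOD_S,
    t0_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of eyes-closed samples per consecutive 8 s block.

    Returns (values, block_start_times_s); a trailing partial block is dropped.
    """
    x = np.asarray(eye_state, float)
    if x.size == 0:
        raise ValueError("empty eye-state stream")
    block = int(round(period_s * rate_hz))
    n_blocks = x.size // block
    if n_blocks == 0:
        raise ValueError("eye-state stream shorter than one block")
    vals = x[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    times = t0_s + period_s * np.arange(n_blocks)
    return vals, times


def detect_valid_yawns(yawns: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Keep yawns with duration strictly greater than 1.5 s, sorted by start."""
    valid = [(s, d) for s, d in yawns if d > YAWN_MIN_DURATION_S]
    return sorted(valid, key=lambda e: e[0])


def perclos_first_difference(
    values: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First difference of successive PERCLOS values, timestamped at the later sample."""
    return np.diff(values), np.asarray(times, float)[1:]


def refine_transitions(
    segment: TransitionSegment, behavior: BehaviorSeries
) -> list[TransitionPoint]:
    """Locate the segment's fatigue-level change times from facial behavior.

    Upward by ``n`` levels: candidates are the times of the ``n`` largest
    PERCLOS first differences plus the starts of the ``n`` earliest valid
    yawns inside the segment; the ``n`` earliest distinct candidate times
    win.  Downward: the ``n`` most negative first differences only.

    Two degeneracies are resolved explicitly.  A first difference only
    qualifies when its sign matches the transition direction (a zero or
    opposite-signed difference carries no evidence of the change), and a
    derivative candidate within one PERCLOS block (8 s) of a yawn
    candidate is treated as the same behavioral event -- PERCLOS time
    stamps are only resolved to the block length, yawn onsets are finer.
    Falls back to the segment midpoint, flagged low-confidence, when there
    are not enough candidates.
    """
    n = segment.n_steps
    t0, t1 = segment.t_start_s, segment.t_end_s
    d_all, dt_all = perclos_first_difference(behavior.perclos, behavior.perclos_times_s)
    keep = (dt_all > t0) & (dt_all < t1)
    d, dt = d_all[keep], dt_all[keep]

    direction = segment.direction
    sign_ok = d > 0 if direction == "up" else d < 0
    d, dt = d[sign_ok], dt[sign_ok]
    candidates: list[tuple[float, str]] = []
    if d.size:
        # earliest time wins on ties: stable sort on (value, time)
        if direction == "up":
            order = np.lexsort((dt, -d))
        else:
            order = np.lexsort((dt, d))
        take = order[: min(n, d.size)]
        candidates += [(float(dt[i]), "perclos_derivative") for i in take]
    if direction == "up":
        yawns = [s for s, _ in detect_valid_yawns(behavior.yawns) if t0 < s < t1]
        yawn_times = yawns[:n]
        candidates = [
            (t, ev)
            for t, ev in candidates
            if all(abs(t - y) > PERCLOS_PERIOD_S for y in yawn_times)
        ]
        candidates += [(s, "yawn") for s in yawn_times]

    # deduplicate identical timestamps, earliest first
    seen: dict[float, str] = {}
    for t, ev in sorted(candidates, key=lambda c: c[0]):
        seen.setdefault(t, ev)
    chosen = sorted(seen.items())[:n]

    points: list[TransitionPoint] = [
        TransitionPoint(t, direction, ev) for t, ev in chosen
    ]
    while len(points) < n:  # no usable behavioral evidence: flag the fallback
        t_mid = 0.5 * (t0 + t1)
        while any(abs(p.time_s - t_mid) < 1e-9 for p in points):
            t_mid += 1.0
        points.append(TransitionPoint(t_mid, direction, "segment_boundary", True))
    points.sort(key=lambda p: p.time_s)
    return points


def build_timeline(
    reports: list[tuple[float, int]],
    behavior: BehaviorSeries,
    windows: WindowConfig | None = None,
) -> StageTimeline:
    """Coarse self-report segmentation refined by facial behavior.

    The span before the first report inherits the first report's level; the
    span after the last report (if any) inherits the last level.
    """
    windows = windows or WindowConfig()
    drive_start = windows.rest_s
    drive_end = windows.rest_s + windows.drive_s
    levels = fisa_to_levels(reports)
    _, segments = segment_intervals(levels)

    transitions: list[TransitionPoint] = []
    for seg in segments:
        pts = refine_transitions(seg, behavior)
        step = 1 if seg.direction == "up" else -1
        level = STAGE_INDEX[seg.level_start]
        for p in pts:
            level += step
            transitions.append(p)
    transitions.sort(key=lambda p: p.time_s)

    # walk the drive, switching level at each refined transition point
    level = STAGE_INDEX[levels[0][1]]
    intervals: list[Interval] = []
    cursor = drive_start
    for p in transitions:
        t = min(max(p.time_s, drive_start), drive_end)
        if t > cursor:
            intervals.append(Interval(cursor, t, _LEVEL_NAME[level]))
            cursor = t
        level += 1 if p.direction == "up" else -1
        level = min(max(level, 1), 3)
    if cursor < drive_end:
        intervals.append(Interval(cursor, drive_end, _LEVEL_NAME[level]))

    # merge any zero-length or like-labeled neighbours
    merged: list[Interval] = []
    for itv in intervals:
        if merged and merged[-1].label == itv.label:
            merged[-1].end_s = itv.end_s
        else:
            merged.append(itv)
    tl = StageTimeline(merged, transitions)
    tl.validate(drive_start, drive_end)
    return tl


def assign_windows(
    timeline: StageTimeline, windows: WindowConfig | None = None
) -> list[tuple[float, str]]:
    """Label each non-overlapping 30 s driving window by its midpoint's stage.

    Returns (window_midpoint_s, stage) pairs; a midpoint exactly on a
    transition boundary takes the later stage (``label_at`` uses half-open
    intervals).  A trailing partial window is discarded.
    """
    windows = windows or WindowConfig()
    w = windows.window_s
    start = windows.rest_s
    n_full = int(windows.drive_s // w)
    out = []
    for k in range(n_full):
        mid = start + k * w + w / 2.0
        label = timeline.label_at(mid)
        out.append((mid, label if label is not None else "unassigned"))
    return out
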