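import numpy as np
import pytest

from volscroll import (
    QuestionLog,
    RelevantRegion,
    ScrollEvent,
    VolumeGeometry,
)


@pytest.fixture
def geometry_z100() -> VolumeGeometry:
    return VolumeGeometry({"z": 100})


@pytest.fixture
def geometry_xyz() -> VolumeGeometry:
    return VolumeGeometry({"x": 40, "y": 50, "z": 100})


def make_log(points, end_ms=None, axis="z", resident="r1", drpt="d1", question="q1"):
    """Build a QuestionLog from (time, slice) pairs (or (time, axis, slice))."""
    events = []
    for p in points:
        if len(p) == 2:
            t, s = p
            a = axis
        else:
            t, a, s = p
        events.append(ScrollEvent(int(t), a, int(s), "scroll"))
    if end_ms is None:
        end_ms = events[-1].time_ms
    return QuestionLog(resident, drpt, question, events, int(end_ms)).validate()


def random_log(rng, n_slices=30, max_events=50, axes=("z",), with_other=False):
    """A random but valid trajectory for oracle-equivalence testing."""
    n_events = int(rng.integers(1, max_events + 1))
    t = 0
    events = []
    ax = str(rng.choice(axes))
    for i in range(n_events):
        if i > 0:
            t += int(rng.integers(1, 500))
            if len(axes) > 1 and rng.random() < 0.1:
                ax = str(rng.choice(axes))
        events.append(ScrollEvent(t, ax, int(rng.integers(1, n_slices + 1)), "scroll"))
        if with_other and rng.random() < 0.2:
            events.append(ScrollEvent(t + int(rng.integers(0, 300)), None, None, "other"))
    # 'other' events may run past display events; question end covers all
    end = max(ev.time_ms for ev in events) + int(rng.integers(1, 1000))
    events.sort(key=lambda ev: ev.time_ms)
    # drop non-display events before first display event to satisfy contract
    while events and not events[0].is_display:
        events.pop(0)
    from volscroll.logio import normalize_events

    return QuestionLog("r", "d", "q", normalize_events(events), end).validate()


# ---------------------------------------------------------------------------
# brute-force reference implementations (independent oracles)
# ---------------------------------------------------------------------------


def brute_force_runs(times, slices, n_slices, t_end):
    """Reference run segmentation: scan every index for direction reversals
    on the plateau-collapsed sequence; apply the strict >50% threshold."""
    pts = [(times[0], slices[0])]
    for t, s in zip(times[1:], slices[1:]):
        if s != pts[-1][1]:
            pts.append((t, s))
    if len(pts) == 1:
        return [(pts[0][0], t_end, 0, False)]
    ext = [pts[0]]
    for i in range(1, len(pts) - 1):
        before = pts[i][1] - pts[i - 1][1]
        after = pts[i + 1][1] - pts[i][1]
        if (before > 0) != (after > 0):
            ext.append(pts[i])
    ext.append(pts[-1])
    runs = []
    for (t0, s0), (t1, s1) in zip(ext[:-1], ext[1:]):
        runs.append((t0, t1, abs(s1 - s0), abs(s1 - s0) > 0.5 * n_slices))
    if t_end > ext[-1][0]:
        runs.append((ext[-1][0], t_end, 0, False))
    return runs


def brute_force_relevant_ms(log, relevant: RelevantRegion) -> int:
    """Reference relevant dwell: simulate the display state millisecond by
    millisecond over [0, question_end_ms)."""
    display = log.display_events
    total = 0
    for ms in range(log.question_end_ms):
        state = None
        for ev in display:
            if ev.time_ms <= ms:
                state = ev
            else:
                break
        if state is not None and relevant.contains(state.axis, state.slice_index):
            total += 1
    return total
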