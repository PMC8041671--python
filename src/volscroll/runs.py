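"""Run segmentation of CT-stack scroll trajectories.

A *run* is the scroll movement between two consecutive local extrema of the
slice-number trajectory on a single viewing axis.  A run whose slice span
exceeds 50% of that axis's slice count (strictly) is a *full run* — the
behavioural proxy for global, holistic search; everything else is an
oscillation or a stationary segment.  ``PercTimeFullRuns`` is the summed
duration of all full runs divided by the total time spent on the question,
times 100.

Segmentation conventions (stated once, used everywhere):

* Runs never span an axis change; each maximal single-axis *episode* is
  segmented on its own, against its own axis's slice count.
* Plateaus (repeated slice values) collapse to the plateau's first
  timestamp before reversal detection, so sampled piecewise-constant logs
  produce no spurious extrema.
* Run k lasts from the timestamp of extremum k to that of extremum k+1;
  consecutive runs share boundary instants, so run durations tile each
  episode exactly.  Trailing dwell after the last extremum (and any fully
  stationary episode) is emitted as a zero-span stationary run — never a
  full run — which makes the durations sum to ``question_end_ms`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import (
    QuestionLog,
    UndefinedMetricError,
    ValidationError,
    VolumeGeometry,
)


@dataclass(frozen=True)
class Episode:
    """A maximal single-axis stretch of the display-state trajectory.

    ``times_ms``/``slices`` are the display samples inside the episode;
    the episode owns the half-open time span ``[t_start_ms, t_end_ms)``
    (the last episode is closed at ``question_end_ms``).
    """

    axis: str
    times_ms: np.ndarray
    slices: np.ndarray
    t_start_ms: int
    t_end_ms: int


@dataclass(frozen=True)
class Run:
    axis: str
    t_start_ms: int
    t_end_ms: int
    slice_start: int
    slice_end: int
    is_full: bool

    @property
    def delta_slices(self) -> int:
        return abs(self.slice_end - self.slice_start)

    @property
    def duration_ms(self) -> int:
        return self.t_end_ms - self.t_start_ms


@dataclass(frozen=True)
class RunProfile:
    runs: tuple[Run, ...]
    total_time_ms: int
    full_run_time_ms: int

    @property
    def perc_time_full_runs(self) -> float:
        if self.total_time_ms <= 0:
            raise UndefinedMetricError("total time is zero")
        return 100.0 * self.full_run_time_ms / self.total_time_ms

    @property
    def n_full_runs(self) -> int:
        return sum(r.is_full for r in self.runs)


def axis_episodes(log: QuestionLog) -> list[Episode]:
    """Split the display trajectory into maximal single-axis episodes.

    Episode time spans partition ``[0, question_end_ms]``: each episode
    starts at its first display event and ends where the next episode
    starts (the last ends at ``question_end_ms``).
    """
    display = log.display_events
    if not display:
        raise ValidationError("log has no display events")
    times = np.array([ev.time_ms for ev in display], dtype=np.int64)
    slices = np.array([ev.slice_index for ev in display], dtype=np.int64)
    axes = [ev.axis for ev in display]
    boundaries = [0] + [i for i in range(1, len(axes)) if axes[i] != axes[i - 1]]
    boundaries.append(len(axes))
    episodes: list[Episode] = []
    for b, e in zip(boundaries[:-1], boundaries[1:]):
        t_end = int(times[e]) if e < len(axes) else log.question_end_ms
        episodes.append(
            Episode(
                axis=axes[b],
                times_ms=times[b:e],
                slices=slices[b:e],
                t_start_ms=int(times[b]),
                t_end_ms=t_end,
            )
        )
    return episodes


def _collapse_plateaus(episode: Episode) -> tuple[np.ndarray, np.ndarray]:
    """Drop repeated slice values, keeping each plateau's first timestamp."""
    s = episode.slices
    keep = np.ones(len(s), dtype=bool)
    keep[1:] = s[1:] != s[:-1]
    return episode.times_ms[keep], s[keep]


def find_extrema(episode: Episode) -> list[tuple[int, int]]:
    """Local extrema (time, slice) of the episode's slice trajectory.

    The first and last distinct displayed positions are always extrema;
    interior extrema are direction reversals.  A stationary episode yields
    a single extremum.
    """
    t, s = _collapse_plateaus(episode)
    if len(s) == 1:
        return [(int(t[0]), int(s[0]))]
    d = np.sign(np.diff(s))
    interior = np.nonzero(d[1:] != d[:-1])[0] + 1
    idx = np.concatenate(([0], interior, [len(s) - 1]))
    return [(int(t[i]), int(s[i])) for i in idx]


def segment_runs(episode: Episode, n_slices_axis: int) -> list[Run]:
    """Runs between consecutive extrema, plus trailing stationary dwell.

    ``is_full`` uses the strict threshold ``delta > 0.5 * n_slices_axis``
    ("more than 50% of the slices"): a span of exactly half the stack is
    not a full run.
    """
    extrema = find_extrema(episode)
    runs: list[Run] = []
    for (t0, s0), (t1, s1) in zip(extrema[:-1], extrema[1:]):
        runs.append(
            Run(
                axis=episode.axis,
                t_start_ms=t0,
                t_end_ms=t1,
                slice_start=s0,
                slice_end=s1,
                is_full=abs(s1 - s0) > 0.5 * n_slices_axis,
            )
        )
    last_t, last_s = extrema[-1]
    if episode.t_end_ms > last_t or not runs:
        runs.append(
            Run(
                axis=episode.axis,
                t_start_ms=last_t,
                t_end_ms=episode.t_end_ms,
                slice_start=last_s,
                slice_end=last_s,
                is_full=False,
            )
        )
    return runs


def perc_time_full_runs(log: QuestionLog, geometry: VolumeGeometry) -> RunProfile:
    """Segment every episode of ``log`` and profile full-run time.

    Raises :class:`UndefinedMetricError` when the question time is zero.
    """
    if log.question_end_ms <= 0:
        raise UndefinedMetricError(
            f"question {log.question_id}: total time is zero, "
            "perc_time_full_runs undefined"
        )
    all_runs: list[Run] = []
    for ep in axis_episodes(log):
        if ep.axis not in geometry.n_slices:
            raise ValidationError(f"axis {ep.axis!r} not in geometry")
        all_runs.extend(segment_runs(ep, geometry.n_slices[ep.axis]))
    full_ms = sum(r.duration_ms for r in all_runs if r.is_full)
    return RunProfile(
        runs=tuple(all_runs),
        total_time_ms=log.question_end_ms,
        full_run_time_ms=full_ms,
    )
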