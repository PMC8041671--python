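"""Domain records for scroll-log analysis of volumetric image reading.

The unit of observation is one resident answering one CT-stack question on
one progress test (DRPT).  A viewer logfile records, for that unit, the
viewing axis and displayed slice number at every interaction; everything
downstream (run segmentation, relevant-area dwell, DRPT-level aggregation,
growth models) consumes these records.

Display-state semantics: the (axis, slice) shown at time ``t`` is that of
the latest display event at or before ``t`` and persists until the next
display event or until ``question_end_ms``.  Slice indices are 1-based and
inclusive everywhere; times are integer milliseconds since the question was
first displayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping

AXES = ("x", "y", "z")  # sagittal, coronal, axial
EVENT_KINDS = ("scroll", "axis_change", "other")
QUESTION_FORMATS = ("marker", "multiple_choice", "long_list")


class ValidationError(ValueError):
    """Raised when a record or file violates the documented contracts."""


class UndefinedMetricError(ValueError):
    """Raised when a ratio metric is requested for zero total time."""


@dataclass(frozen=True)
class ScrollEvent:
    """One time-stamped viewer interaction.

    ``event_kind='other'`` covers pan/zoom/window-level events: they are
    parsed and preserved but carry no slice semantics, so ``axis`` and
    ``slice_index`` may be ``None`` for them and they never influence any
    metric.
    """

    time_ms: int
    axis: str | None
    slice_index: int | None
    event_kind: str = "scroll"

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise ValidationError(f"time_ms must be >= 0, got {self.time_ms}")
        if self.event_kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event_kind {self.event_kind!r}")
        if self.event_kind != "other":
            if self.axis not in AXES:
                raise ValidationError(f"axis must be one of {AXES}, got {self.axis!r}")
            if self.slice_index is None or self.slice_index < 1:
                raise ValidationError(
                    f"slice_index must be a 1-based integer, got {self.slice_index!r}"
                )

    @property
    def is_display(self) -> bool:
        """True for events that set the display state (scroll / axis change)."""
        return self.event_kind != "other"


@dataclass(frozen=True)
class VolumeGeometry:
    """Slice counts per viewable axis of one CT stack (metadata only)."""

    n_slices: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_slices", dict(self.n_slices))
        for axis, n in self.n_slices.items():
            if axis not in AXES:
                raise ValidationError(f"unknown axis {axis!r}")
            if n < 2:
                raise ValidationError(f"n_slices[{axis}] must be >= 2, got {n}")
        if not self.n_slices:
            raise ValidationError("geometry must define at least one axis")

    @property
    def viewable_axes(self) -> tuple[str, ...]:
        return tuple(a for a in AXES if a in self.n_slices)


@dataclass(frozen=True)
class RelevantRegion:
    """Expert-defined question-relevant slice intervals, per axis.

    Intervals are inclusive 1-based ``(lo, hi)`` pairs; per axis they are
    normalized to a sorted, disjoint (merged) list.  An axis mapped to an
    empty list is viewable but carries no relevant slices.
    """

    intervals: Mapping[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        norm: dict[str, tuple[tuple[int, int], ...]] = {}
        for axis, ivs in self.intervals.items():
            if axis not in AXES:
                raise ValidationError(f"unknown axis {axis!r}")
            norm[axis] = _merge_intervals(ivs)
        object.__setattr__(self, "intervals", norm)

    def contains(self, axis: str, slice_index: int) -> bool:
        if axis not in self.intervals:
            raise ValidationError(f"axis {axis!r} has no relevance definition")
        return any(lo <= slice_index <= hi for lo, hi in self.intervals[axis])

    def complement(self, geometry: VolumeGeometry) -> "RelevantRegion":
        """The irrelevant region on every axis of ``geometry``."""
        comp: dict[str, list[tuple[int, int]]] = {}
        for axis in geometry.viewable_axes:
            n = geometry.n_slices[axis]
            out: list[tuple[int, int]] = []
            cursor = 1
            for lo, hi in self.intervals.get(axis, ()):
                if lo > cursor:
                    out.append((cursor, lo - 1))
                cursor = hi + 1
            if cursor <= n:
                out.append((cursor, n))
            comp[axis] = out
        return RelevantRegion(comp)

    def validate_against(self, geometry: VolumeGeometry) -> None:
        for axis, ivs in self.intervals.items():
            if axis not in geometry.n_slices:
                raise ValidationError(f"relevant axis {axis!r} not in geometry")
            for lo, hi in ivs:
                if hi > geometry.n_slices[axis]:
                    raise ValidationError(
                        f"interval [{lo},{hi}] exceeds {geometry.n_slices[axis]} "
                        f"slices on axis {axis!r}"
                    )


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    pairs = sorted((int(lo), int(hi)) for lo, hi in ivs)
    for lo, hi in pairs:
        if not 1 <= lo <= hi:
            raise ValidationError(f"bad interval [{lo},{hi}]: need 1 <= lo <= hi")
    merged: list[list[int]] = []
    for lo, hi in pairs:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


@dataclass
class QuestionLog:
    """The full event stream of one resident x question on one DRPT."""

    resident_id: str
    drpt_id: str
    question_id: str
    events: list[ScrollEvent]
    question_end_ms: int

    def validate(self, geometry: VolumeGeometry | None = None) -> "QuestionLog":
        if not self.events:
            raise ValidationError("a question log must contain at least one event")
        first = self.events[0]
        if first.time_ms != 0 or not first.is_display:
            raise ValidationError(
                "first event must be a display event at time 0 "
                "(initial axis and slice)"
            )
        last_t = -1
        last_display_t = -1
        for ev in self.events:
            if ev.time_ms < last_t:
                raise ValidationError("events are not sorted by time_ms")
            if ev.is_display:
                if ev.time_ms <= last_display_t:
                    raise ValidationError(
                        "display events must be strictly increasing in time "
                        "(normalize first)"
                    )
                last_display_t = ev.time_ms
            last_t = ev.time_ms
            if geometry is not None and ev.is_display:
                if ev.axis not in geometry.n_slices:
                    raise ValidationError(
                        f"axis {ev.axis!r} not viewable for this question"
                    )
                n = geometry.n_slices[ev.axis]
                if not 1 <= ev.slice_index <= n:
                    raise ValidationError(
                        f"slice_index {ev.slice_index} outside [1,{n}] "
                        f"on axis {ev.axis!r}"
                    )
        if self.question_end_ms < last_t:
            raise ValidationError("question_end_ms precedes the last event")
        return self

    @property
    def display_events(self) -> list[ScrollEvent]:
        return [ev for ev in self.events if ev.is_display]

    @property
    def total_time_ms(self) -> int:
        return self.question_end_ms


@dataclass(frozen=True)
class QuestionInfo:
    """Static metadata of one selected (or candidate) test question."""

    question_id: str
    format: str
    subdomain: str
    geometry: VolumeGeometry
    relevant: RelevantRegion
    p_value: float
    requires_diagnosis: bool = True
    single_ct: bool = True

    def __post_init__(self) -> None:
        if self.format not in QUESTION_FORMATS:
            raise ValidationError(f"unknown question format {self.format!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value must be in [0,1], got {self.p_value}")


@dataclass(frozen=True)
class Resident:
    """Training window of one radiology resident."""

    resident_id: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValidationError("end_date must follow start_date")


@dataclass(frozen=True)
class DRPTInfo:
    """One semi-annual progress test: date, question set, derived difficulty."""

    drpt_id: str
    date: date
    question_ids: tuple[str, ...] = ()
    drpt_diff: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "question_ids", tuple(self.question_ids))
        if self.drpt_diff is not None and not -0.5 <= self.drpt_diff <= 0.5:
            raise ValidationError(
                f"drpt_diff must lie in [-0.5, 0.5], got {self.drpt_diff}"
            )


@dataclass(frozen=True)
class QuestionMetrics:
    """Per resident x question measurements fed into aggregation."""

    resident_id: str
    drpt_id: str
    question_id: str
    perc_time_full_runs: float
    perc_time_rel_area: float
    total_time_ms: int
    correct: int | None = None

    def __post_init__(self) -> None:
        for name in ("perc_time_full_runs", "perc_time_rel_area"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must be in [0,100], got {v}")
        if self.correct is not None and self.correct not in (0, 1):
            raise ValidationError(f"correct must be 0 or 1, got {self.correct}")


@dataclass(frozen=True)
class DRPTRecord:
    """One resident x DRPT row after aggregation — the modelling unit.

    ``tr_time`` is relative training time on the five-year scale;
    ``drpt_diff`` is the mean item P value of the test's selected questions
    minus 0.5.  The percentage averages are unweighted means over the
    resident's available question logs on that test.
    """

    resident_id: str
    drpt_id: str
    tr_time: float
    drpt_diff: float
    perc_time_full_runs_avg: float
    perc_time_rel_area_avg: float
    n_correct: int
    n_questions: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_questions:
            raise ValidationError(
                f"need 0 <= n_correct <= n_questions, got "
                f"{self.n_correct}/{self.n_questions}"
            )
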