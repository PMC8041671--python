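"""Dwell time on question-relevant slices.

The display state is piecewise constant: the slice shown over ``[t, t')``
is the one set by the display event at ``t``, and the last state persists
until ``question_end_ms``.  ``PercTimeRelArea`` accrues an interval's
duration when the displayed slice lies in a relevant interval of the
*currently displayed* axis — time spent on an axis whose relevant interval
list is empty counts as irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import (
    QuestionLog,
    RelevantRegion,
    UndefinedMetricError,
    ValidationError,
    VolumeGeometry,
)


@dataclass(frozen=True)
class RelevanceProfile:
    relevant_time_ms: int
    total_time_ms: int

    @property
    def perc_time_rel_area(self) -> float:
        if self.total_time_ms <= 0:
            raise UndefinedMetricError("total time is zero")
        return 100.0 * self.relevant_time_ms / self.total_time_ms


def time_in_relevant_area(log: QuestionLog, relevant: RelevantRegion) -> RelevanceProfile:
    """Total and relative dwell time on question-relevant slices.

    Every axis occurring in the log must have an interval list in
    ``relevant`` (an empty list means nothing on that axis is relevant).
    """
    if log.question_end_ms <= 0:
        raise UndefinedMetricError(
            f"question {log.question_id}: total time is zero, "
            "perc_time_rel_area undefined"
        )
    display = log.display_events
    if not display:
        raise ValidationError("log has no display events")
    times = np.array([ev.time_ms for ev in display] + [log.question_end_ms], dtype=np.int64)
    durations = np.diff(times)
    relevant_ms = 0
    for ev, dur in zip(display, durations):
        if ev.axis not in relevant.intervals:
            raise ValidationError(
                f"axis {ev.axis!r} occurs in the log but has no relevance definition"
            )
        if dur > 0 and relevant.contains(ev.axis, ev.slice_index):
            relevant_ms += int(dur)
    return RelevanceProfile(relevant_time_ms=relevant_ms, total_time_ms=log.question_end_ms)


def relevant_volume_fraction(
    relevant: RelevantRegion, geometry: VolumeGeometry, reference_axis: str = "z"
) -> float:
    """Fraction of the stack's slices that are question-relevant.

    Evaluated on ``reference_axis`` (axial by default, the viewer's default
    direction); used by question selection to separate focal from diffuse
    abnormalities.
    """
    if reference_axis not in geometry.n_slices:
        raise ValidationError(f"reference axis {reference_axis!r} not viewable")
    ivs = relevant.intervals.get(reference_axis)
    if ivs is None:
        raise ValidationError(f"no relevance definition on axis {reference_axis!r}")
    covered = sum(hi - lo + 1 for lo, hi in ivs)
    return covered / geometry.n_slices[reference_axis]
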