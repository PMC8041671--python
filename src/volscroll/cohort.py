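"""Question selection, training-time and test-difficulty scaling, scoring,
and aggregation of question-level metrics to resident x DRPT records.

Training time is standardized to the five-year residency scale

    TrTime = (DRPTdate - StartDate) / (EndDate - StartDate) * 5

with date arithmetic in whole days, so residents who trained part-time or
paused progress more slowly on the calendar but comparably on TrTime.

Test difficulty ``DRPTdiff`` is the mean item P value (proportion correct)
of the selected questions of that test minus 0.5, landing on a [-0.5, 0.5]
scale where 0 means half the residents answered correctly and higher means
easier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import (
    DRPTRecord,
    QuestionInfo,
    QuestionMetrics,
    Resident,
    ValidationError,
)
from .relevance import relevant_volume_fraction

FOCAL_VOLUME_THRESHOLD = 0.5  # strict: relevant fraction must be < 50%


def training_time(drpt_date: date, resident: Resident) -> float:
    """Relative training time in years on the five-year scale."""
    span = (resident.end_date - resident.start_date).days
    elapsed = (drpt_date - resident.start_date).days
    return elapsed / span * 5.0


def drpt_difficulty(p_values: Sequence[float]) -> float:
    """Mean item P value minus 0.5 (rescaled test difficulty)."""
    if len(p_values) == 0:
        raise ValidationError("drpt_difficulty needs at least one P value")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("P values must lie in [0,1]")
    return float(p.mean() - 0.5)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the three-criterion question filter."""

    kept: tuple[QuestionInfo, ...]
    rejected_not_single_ct: int
    rejected_no_diagnosis: int
    rejected_diffuse: int
    flagged: tuple[str, ...] = ()  # questions with unusable geometry/region

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def select_questions(
    questions: Iterable[QuestionInfo], reference_axis: str = "z"
) -> SelectionResult:
    """Apply the three selection criteria, in order.

    Keep a question iff it (1) concerns a single CT scan, (2) requires a
    diagnosis (not mere anatomy marking), and (3) has a question-relevant
    volume covering strictly less than 50% of the stack on the reference
    axis (focal, not diffuse, abnormality).  Questions whose geometry or
    region cannot be evaluated are flagged, never silently dropped.
    """
    kept: list[QuestionInfo] = []
    flagged: list[str] = []
    n_ct = n_diag = n_diffuse = 0
    for q in questions:
        if not q.single_ct:
            n_ct += 1
            continue
        if not q.requires_diagnosis:
            n_diag += 1
            continue
        try:
            frac = relevant_volume_fraction(q.relevant, q.geometry, reference_axis)
        except ValidationError:
            flagged.append(q.question_id)
            continue
        if frac < FOCAL_VOLUME_THRESHOLD:
            kept.append(q)
        else:
            n_diffuse += 1
    return SelectionResult(
        kept=tuple(kept),
        rejected_not_single_ct=n_ct,
        rejected_no_diagnosis=n_diag,
        rejected_diffuse=n_diffuse,
        flagged=tuple(flagged),
    )


def aggregate_to_drpt(
    metrics: Iterable[QuestionMetrics],
    residents: Mapping[str, Resident],
    drpt_dates: Mapping[str, date],
    drpt_diffs: Mapping[str, float],
    exclude_formats: frozenset[str] | set[str] = frozenset(),
    question_formats: Mapping[str, str] | None = None,
) -> list[DRPTRecord]:
    """Aggregate question-level metrics to one record per resident x DRPT.

    Scroll percentages are unweighted means over the questions with an
    available logfile (missing logfiles were dropped listwise upstream and
    simply do not appear here).  ``n_correct``/``n_questions`` count only
    questions whose format is not in ``exclude_formats`` (the accuracy
    models drop marker questions); the scroll averages always include every
    available question.  Residents without a usable training window must be
    excluded before calling (they never reach this table).  A resident x
    DRPT cell with zero available questions is omitted with a warning.
    """
    exclude = frozenset(exclude_formats)
    if exclude and question_formats is None:
        raise ValidationError("exclude_formats requires question_formats")
    cells: dict[tuple[str, str], list[QuestionMetrics]] = {}
    for m in metrics:
        cells.setdefault((m.resident_id, m.drpt_id), []).append(m)
    records: list[DRPTRecord] = []
    for (rid, did), ms in sorted(cells.items()):
        if not ms:
            warnings.warn(f"resident {rid} x DRPT {did}: no available questions; omitted")
            continue
        if rid not in residents:
            raise ValidationError(f"metrics reference unknown resident {rid!r}")
        if did not in drpt_dates:
            raise ValidationError(f"metrics reference unknown DRPT {did!r}")
        scored = [
            m
            for m in ms
            if m.correct is not None
            and (not exclude or question_formats.get(m.question_id) not in exclude)
        ]
        records.append(
            DRPTRecord(
                resident_id=rid,
                drpt_id=did,
                tr_time=training_time(drpt_dates[did], residents[rid]),
                drpt_diff=drpt_diffs[did],
                perc_time_full_runs_avg=float(
                    np.mean([m.perc_time_full_runs for m in ms])
                ),
                perc_time_rel_area_avg=float(
                    np.mean([m.perc_time_rel_area for m in ms])
                ),
                n_correct=sum(m.correct for m in scored),
                n_questions=len(scored),
            )
        )
    return records
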