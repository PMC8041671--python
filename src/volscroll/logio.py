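"""Reading, normalizing and writing viewer logfiles and cohort tables.

Logfile dialect
---------------
Delimited UTF-8 text, one event per row, header required::

    time_ms,axis,slice_index,event_kind

``axis`` and ``slice_index`` may be empty for ``event_kind=other`` rows
(pan/zoom/window-level events), which are preserved verbatim but ignored by
every metric.  One file per resident x question, named
``<resident>__<drpt>__<question>.log.csv``.

Normalization shifts all times so the first event sits at 0 and, among
display events sharing one timestamp, keeps only the last (the display
state is single-valued).  Normalization is idempotent.

Cohort tables are plain CSV: ``residents.csv``, ``drpts.csv``,
``questions.csv``, ``regions.csv`` (one interval per row) and
``answers.csv`` with 0/1 correctness.
"""

from __future__ import annotations

import csv
import math
from datetime import date
from pathlib import Path

import pandas as pd

from .records import (
    AXES,
    EVENT_KINDS,
    DRPTInfo,
    QuestionInfo,
    QuestionLog,
    RelevantRegion,
    Resident,
    ScrollEvent,
    ValidationError,
    VolumeGeometry,
)

LOG_COLUMNS = ("time_ms", "axis", "slice_index", "event_kind")


class ParseError(ValueError):
    """A malformed logfile row; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str) -> None:
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def log_filename(resident_id: str, drpt_id: str, question_id: str) -> str:
    return f"{resident_id}__{drpt_id}__{question_id}.log.csv"


def parse_log_filename(name: str) -> tuple[str, str, str]:
    stem = name
    if stem.endswith(".log.csv"):
        stem = stem[: -len(".log.csv")]
    parts = stem.split("__")
    if len(parts) != 3:
        raise ValidationError(f"logfile name {name!r} is not <res>__<drpt>__<q>.log.csv")
    return parts[0], parts[1], parts[2]


def normalize_events(events: list[ScrollEvent]) -> list[ScrollEvent]:
    """Shift times to start at 0; collapse simultaneous display events.

    Among display events with equal ``time_ms`` only the last survives
    (single-valued display state); ``other`` events pass through untouched.
    Idempotent.
    """
    if not events:
        return []
    display = [ev for ev in events if ev.is_display]
    if not display:
        raise ValidationError("log contains no display events")
    offset = display[0].time_ms
    last_at: dict[int, int] = {}
    for i, ev in enumerate(events):
        if ev.is_display:
            last_at[ev.time_ms] = i
    out: list[ScrollEvent] = []
    for i, ev in enumerate(events):
        t = ev.time_ms - offset
        if t < 0:
            raise ValidationError("display events must not be preceded by other events")
        if ev.is_display and last_at[ev.time_ms] != i:
            continue  # a later display event shares this timestamp
        out.append(
            ev if offset == 0 else ScrollEvent(t, ev.axis, ev.slice_index, ev.event_kind)
        )
    return out


def read_question_log(
    path, geometry: VolumeGeometry, *, ids: tuple[str, str, str] | None = None
) -> QuestionLog:
    """Read one logfile, validate it against ``geometry`` and normalize it.

    The final row may be a special ``end`` row (``time_ms,,,end``) giving
    ``question_end_ms``; otherwise the last event's timestamp is taken as
    the question end.
    """
    path = Path(path)
    resident_id, drpt_id, question_id = ids or parse_log_filename(path.name)
    events: list[ScrollEvent] = []
    end_ms: int | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(LOG_COLUMNS):
            raise ParseError(path, 1, f"expected header {','.join(LOG_COLUMNS)}")
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ParseError(path, line_no, f"expected 4 fields, got {len(row)}")
            t_raw, axis_raw, slice_raw, kind = (c.strip() for c in row)
            try:
                t = int(t_raw)
            except ValueError:
                raise ParseError(path, line_no, f"bad time_ms {t_raw!r}") from None
            if kind == "end":
                end_ms = t
                continue
            if kind not in EVENT_KINDS:
                raise ParseError(path, line_no, f"unknown event_kind {kind!r}")
            axis = axis_raw or None
            if axis is not None and axis not in AXES:
                raise ParseError(path, line_no, f"axis must be one of {AXES}, got {axis!r}")
            slice_index: int | None = None
            if slice_raw:
                try:
                    slice_index = int(slice_raw)
                except ValueError:
                    raise ParseError(path, line_no, f"bad slice_index {slice_raw!r}") from None
            try:
                ev = ScrollEvent(t, axis, slice_index, kind)
            except ValidationError as exc:
                raise ParseError(path, line_no, str(exc)) from None
            if events and ev.time_ms < events[-1].time_ms:
                raise ParseError(path, line_no, "events are not sorted by time_ms")
            events.append(ev)
    if not events:
        raise ParseError(path, 1, "logfile contains no events")
    display = [ev for ev in events if ev.is_display]
    if not display:
        raise ParseError(path, 1, "logfile contains no display events")
    offset = display[0].time_ms  # end row shares the raw clock of the events
    events = normalize_events(events)
    end_ms = events[-1].time_ms if end_ms is None else end_ms - offset
    log = QuestionLog(resident_id, drpt_id, question_id, events, end_ms)
    return log.validate(geometry)


def write_question_log(log: QuestionLog, path) -> None:
    """Write a normalized log in the documented dialect (round-trips)."""
    log.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for ev in log.events:
            writer.writerow(
                [
                    ev.time_ms,
                    ev.axis or "",
                    "" if ev.slice_index is None else ev.slice_index,
                    ev.event_kind,
                ]
            )
        writer.writerow([log.question_end_ms, "", "", "end"])


def _parse_date(s: str, context: str) -> date:
    try:
        return date.fromisoformat(str(s).strip())
    except ValueError:
        raise ValidationError(f"{context}: bad ISO-8601 date {s!r}") from None


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
        return None
    return int(float(v))


def read_cohort(tables_dir):
    """Load the cohort tables and resolve all cross-references.

    Returns ``(residents, drpts, questions, answers)`` where the first three
    are dicts keyed by id and ``answers`` is a DataFrame with columns
    ``resident_id, drpt_id, question_id, correct``.  Dangling references or
    non-0/1 answers raise :class:`ValidationError` naming the offending keys.
    """
    tables_dir = Path(tables_dir)

    res_df = pd.read_csv(tables_dir / "residents.csv", dtype=str)
    residents: dict[str, Resident] = {}
    for row in res_df.itertuples(index=False):
        rid = str(row.resident_id)
        residents[rid] = Resident(
            rid,
            _parse_date(row.start_date, f"resident {rid}"),
            _parse_date(row.end_date, f"resident {rid}"),
        )

    drpt_df = pd.read_csv(tables_dir / "drpts.csv", dtype=str)
    drpts: dict[str, DRPTInfo] = {}
    for row in drpt_df.itertuples(index=False):
        did = str(row.drpt_id)
        drpts[did] = DRPTInfo(did, _parse_date(row.date, f"drpt {did}"))

    regions_path = tables_dir / "regions.csv"
    region_rows = pd.read_csv(regions_path) if regions_path.exists() else pd.DataFrame(
        columns=["question_id", "axis", "lo", "hi"]
    )
    intervals_by_q: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for row in region_rows.itertuples(index=False):
        qiv = intervals_by_q.setdefault(str(row.question_id), {})
        qiv.setdefault(str(row.axis), []).append((int(row.lo), int(row.hi)))

    q_df = pd.read_csv(tables_dir / "questions.csv")
    questions: dict[str, QuestionInfo] = {}
    for row in q_df.itertuples(index=False):
        qid = str(row.question_id)
        n_slices = {}
        for axis in AXES:
            n = _opt_int(getattr(row, f"n_slices_{axis}", None))
            if n is not None:
                n_slices[axis] = n
        geometry = VolumeGeometry(n_slices)
        ivs = intervals_by_q.get(qid, {})
        relevant = RelevantRegion(
            {axis: tuple(ivs.get(axis, [])) for axis in geometry.viewable_axes}
        )
        relevant.validate_against(geometry)
        questions[qid] = QuestionInfo(
            question_id=qid,
            format=str(row.format),
            subdomain=str(getattr(row, "subdomain", "unknown")),
            geometry=geometry,
            relevant=relevant,
            p_value=float(row.p_value),
            requires_diagnosis=_as_bool(getattr(row, "requires_diagnosis", True)),
            single_ct=_as_bool(getattr(row, "single_ct", True)),
        )

    dangling_regions = sorted(set(intervals_by_q) - set(questions))
    if dangling_regions:
        raise ValidationError(f"regions.csv references unknown questions: {dangling_regions}")

    answers = pd.read_csv(
        tables_dir / "answers.csv",
        dtype={"resident_id": str, "drpt_id": str, "question_id": str},
    )
    bad = answers.loc[~answers["correct"].isin([0, 1])]
    if not bad.empty:
        raise ValidationError(
            f"answers must be 0/1; offending rows: {bad.head().to_dict('records')}"
        )
    for col, known in (
        ("resident_id", residents),
        ("drpt_id", drpts),
        ("question_id", questions),
    ):
        missing = sorted(set(answers[col]) - set(known))
        if missing:
            raise ValidationError(f"answers reference unknown {col}s: {missing}")
    answers = answers.astype({"correct": int})
    return residents, drpts, questions, answers


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def write_cohort(tables_dir, residents, drpts, questions, answers: pd.DataFrame) -> None:
    """Write the cohort tables in the format :func:`read_cohort` consumes."""
    tables_dir = Path(tables_dir)
    tables_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "resident_id": r.resident_id,
                "start_date": r.start_date.isoformat(),
                "end_date": r.end_date.isoformat(),
            }
            for r in residents.values()
        ]
    ).to_csv(tables_dir / "residents.csv", index=False)
    pd.DataFrame(
        [{"drpt_id": d.drpt_id, "date": d.date.isoformat()} for d in drpts.values()]
    ).to_csv(tables_dir / "drpts.csv", index=False)
    q_rows, region_rows = [], []
    for q in questions.values():
        row = {
            "question_id": q.question_id,
            "format": q.format,
            "subdomain": q.subdomain,
            "p_value": q.p_value,
            "requires_diagnosis": q.requires_diagnosis,
            "single_ct": q.single_ct,
        }
        for axis in AXES:
            row[f"n_slices_{axis}"] = q.geometry.n_slices.get(axis, "")
        q_rows.append(row)
        for axis, ivs in q.relevant.intervals.items():
            for lo, hi in ivs:
                region_rows.append(
                    {"question_id": q.question_id, "axis": axis, "lo": lo, "hi": hi}
                )
    pd.DataFrame(q_rows).to_csv(tables_dir / "questions.csv", index=False)
    pd.DataFrame(region_rows, columns=["question_id", "axis", "lo", "hi"]).to_csv(
        tables_dir / "regions.csv", index=False
    )
    answers.to_csv(tables_dir / "answers.csv", index=False)
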