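"""Synthetic scroll logs and synthetic cohorts.

Two levels of simulation make every pipeline stage testable without access
to the (non-public) progress-test logfiles:

* **micro** — :func:`simulate_trajectory` emits a single question's event
  stream with controllable full-run and relevant-area time structure:
  initial full sweeps through the whole stack (the global-impression
  phase), then oscillations concentrated on the question-relevant slices,
  then dwell on irrelevant slices.  The synthesis is exact up to event
  quantization, so pipeline metrics converge to the generating targets as
  noise goes to zero.

* **macro** — :func:`simulate_cohort` draws resident x DRPT records from
  the two-level models that the study's result tables parameterize:
  Gaussian DRPT-level scroll outcomes with resident random intercepts, and
  binomial accuracy through a logit link.  Default fixed effects and
  variance components are the published Model 2 estimates for each outcome.

:func:`simulate_micro_cohort` composes the two: macro records supply per
resident x DRPT targets, trajectories realize them per question, and the
result is a complete on-disk (or in-memory) fixture the full pipeline can
consume end to end.

Default study conditions (all overridable): 9 semi-annual tests between
September 2013 and April 2018 with the autumn-2015 test missing; about five
selected CT questions per test (min 2, max 9); a mean of 122.9 s spent per
CT question; test difficulty averaging 0.14 on the [-0.5, 0.5] scale
(sd 0.07, observed range 0.02-0.24); roughly 300 participants per test
drawn from ~650 residents who each sit between 1 and 9 tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import training_time
from .logio import log_filename, write_cohort, write_question_log
from .records import (
    DRPTInfo,
    DRPTRecord,
    QuestionInfo,
    QuestionLog,
    RelevantRegion,
    Resident,
    ScrollEvent,
    ValidationError,
    VolumeGeometry,
)

DRPT_DATES: tuple[date, ...] = (
    date(2013, 9, 26),
    date(2014, 4, 10),
    date(2014, 9, 25),
    date(2015, 4, 9),
    # the autumn 2015 test failed for technical reasons and yields no data
    date(2016, 4, 7),
    date(2016, 9, 22),
    date(2017, 4, 6),
    date(2017, 9, 21),
    date(2018, 4, 12),
)

#: Published Model 2 estimates used as generator defaults, per outcome:
#: (intercept, b_TrTime, b_DRPTdiff, sigma2_e, sigma2_u0)
FULLRUNS_PARAMS = (20.19, -0.94, 6.70, 81.56, 10.84)
RELAREA_PARAMS = (53.16, 1.70, -57.47, 133.04, 5.30)
#: Accuracy model: (intercept, b_TrTime, b_FullRunsAvg, b_RelAreaAvg,
#: b_DRPTdiff, sigma2_u0); level-1 variance is binomial.
ACCURACY_PARAMS = (-1.078, 0.338, 0.001, 0.003, 5.093, 0.056)


class InfeasibleTargetError(ValidationError):
    """The requested full-run / relevant-area time pair cannot coexist."""


@dataclass(frozen=True)
class TrajectoryParams:
    """Targets and timing for one synthetic question trajectory."""

    geometry: VolumeGeometry
    relevant: RelevantRegion
    target_perc_full_runs: float
    target_perc_rel_area: float
    mean_question_time_ms: int = 122_900  # study mean: 122.9 s per CT question
    noise_sd: float = 0.0  # sd (percent points) of target jitter, per metric
    min_step_ms: int = 30  # fastest credible per-slice scroll step
    axis: str = "z"  # axial is the viewer default
    expertise: float | None = None  # training years; informational
    resident_intercepts: tuple[float, float] | None = None  # informational

    def __post_init__(self) -> None:
        for t in (self.target_perc_full_runs, self.target_perc_rel_area):
            if not 0.0 <= t <= 100.0:
                raise ValidationError(f"targets must be in [0,100], got {t}")
        if self.mean_question_time_ms <= 0:
            raise ValidationError("mean_question_time_ms must be positive")


@dataclass(frozen=True)
class CohortParams:
    """Population and model parameters for macro-level cohort simulation."""

    n_residents: int = 650
    drpt_dates: tuple[date, ...] = DRPT_DATES
    enrolment_start: date = date(2008, 6, 1)
    enrolment_end: date = date(2018, 3, 1)
    duration_years_range: tuple[float, float] = (5.0, 6.5)  # calendar pace
    participation_prob: float = 0.86  # not every eligible resident sat every test
    questions_per_drpt: tuple[int, int] = (2, 9)  # binomial(7, 3/7)+2: mean 5
    fullruns: tuple[float, float, float, float, float] = FULLRUNS_PARAMS
    relarea: tuple[float, float, float, float, float] = RELAREA_PARAMS
    accuracy: tuple[float, float, float, float, float, float] = ACCURACY_PARAMS
    drpt_diff_mean: float = 0.14
    drpt_diff_sd: float = 0.07
    drpt_diff_range: tuple[float, float] = (0.02, 0.24)

    def __post_init__(self) -> None:
        lo, hi = self.questions_per_drpt
        if not (1 <= lo <= hi):
            raise ValidationError("questions_per_drpt bounds must satisfy 1 <= lo <= hi")


# ---------------------------------------------------------------------------
# micro level: one trajectory
# ---------------------------------------------------------------------------


def _sweep_events(t0: int, duration: int, s_from: int, s_to: int, min_step: int):
    """Monotone sweep s_from -> s_to over [t0, t0+duration); integer times."""
    n_steps = abs(s_to - s_from)
    k = max(2, min(n_steps + 1, duration // max(min_step, 1) or 2))
    slices = np.linspace(s_from, s_to, k).round().astype(int)
    times = t0 + np.floor(np.arange(k) * duration / k).astype(int)
    return times, slices


def _oscillation_events(t0: int, duration: int, a: int, b: int, min_step: int):
    """Bounce between a and b inside [t0, t0+duration), starting at a."""
    if duration <= 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    if a == b:
        return np.array([t0]), np.array([a])
    span = abs(b - a)
    step = 1 if b > a else -1
    n_events = max(2, min(duration // max(min_step, 1), 4 * span + 2))
    pattern = np.concatenate([np.arange(a, b + step, step), np.arange(b - step, a, -step)])
    slices = np.resize(pattern, n_events)
    times = t0 + np.floor(np.arange(n_events) * duration / n_events).astype(int)
    return times, slices


def _anchored_range(
    intervals, prev_range: tuple[int, int] | None, n: int
) -> tuple[int, int]:
    """An oscillation range inside one of ``intervals``, anchored near the
    previous segment's slices and capped so the approach merged with the
    first oscillation leg never spans more than half the stack.

    A run ends only at a direction reversal, so a movement entering this
    segment can reach back to the previous segment's lowest (when ascending)
    or highest (when descending) slice; the span cap uses that worst case.
    """
    def dist_to(iv):
        lo, hi = iv
        if prev_range is None:
            return 0
        cur = (prev_range[0] + prev_range[1]) // 2
        if lo <= cur <= hi:
            return 0
        return min(abs(cur - lo), abs(cur - hi))

    lo, hi = min(intervals, key=dist_to)
    cur = None if prev_range is None else (prev_range[0] + prev_range[1]) // 2
    if cur is None or abs(cur - lo) <= abs(cur - hi):
        anchor, inward = lo, 1
    else:
        anchor, inward = hi, -1
    if prev_range is None:
        reach = 0
    elif inward > 0:
        reach = max(0, anchor - prev_range[0])
    else:
        reach = max(0, prev_range[1] - anchor)
    span = min(hi - lo, (n - 1) // 2, max(0, n // 2 - reach))
    return anchor, anchor + inward * span


def simulate_trajectory(
    params: TrajectoryParams, seed: int | np.random.Generator = 0
) -> tuple[QuestionLog, dict]:
    """Emit one synthetic question log realizing the requested time shares.

    Returns ``(log, truth)`` where ``truth`` holds the jittered targets the
    trajectory was built to, the question time, and the axis used.  Raises
    :class:`InfeasibleTargetError` when the pair of targets cannot coexist
    on the given relevant region (e.g. 100% full runs with 100% relevance
    on a region smaller than the stack).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    axis = params.axis
    if axis not in params.geometry.n_slices:
        raise ValidationError(f"axis {axis!r} not in geometry")
    n = params.geometry.n_slices[axis]
    ivs = params.relevant.intervals.get(axis)
    if ivs is None:
        raise ValidationError(f"no relevance definition on axis {axis!r}")
    rel_len = sum(hi - lo + 1 for lo, hi in ivs)

    f = float(np.clip(params.target_perc_full_runs + rng.normal(0, params.noise_sd), 0, 100))
    r = float(np.clip(params.target_perc_rel_area + rng.normal(0, params.noise_sd), 0, 100))
    total = int(params.mean_question_time_ms)

    full_ms = int(round(f / 100 * total))
    rel_ms = int(round(r / 100 * total))
    sweep_rel_ms = int(round(full_ms * rel_len / n))  # sweeps cross the region too
    osc_rel_ms = rel_ms - sweep_rel_ms
    rest_ms = total - full_ms
    irrel_ms = rest_ms - osc_rel_ms
    if osc_rel_ms < 0:
        raise InfeasibleTargetError(
            f"full runs alone already spend {100 * sweep_rel_ms / total:.1f}% of time "
            f"on the relevant region, above the {r:.1f}% target"
        )
    if irrel_ms < 0:
        raise InfeasibleTargetError(
            f"targets need {f:.1f}% full-run time plus {100 * osc_rel_ms / total:.1f}% "
            "extra relevant dwell: more than the question time"
        )
    if osc_rel_ms > 0 and rel_len == 0:
        raise InfeasibleTargetError("relevant dwell requested but the region is empty")
    comp = params.relevant.complement(params.geometry).intervals.get(axis, ())
    if irrel_ms > 0 and not comp:
        raise InfeasibleTargetError(
            "irrelevant dwell required but the whole stack is relevant"
        )

    times: list[np.ndarray] = []
    slices: list[np.ndarray] = []
    t = 0
    prev_range: tuple[int, int] | None = None
    # (i) initial full sweeps: each spans n-1 > n/2 slices; oriented so the
    # last sweep ends at the stack end nearest the next segment's region
    if full_ms > 0:
        next_region = ivs if osc_rel_ms > 0 else (comp if irrel_ms > 0 else None)
        end_at = 1
        if next_region:
            lo0, hi0 = min(next_region, key=lambda iv: iv[0])
            end_at = 1 if (lo0 - 1) <= (n - max(hi for _, hi in next_region)) else n
        n_sweeps = 1 if full_ms <= 2 * n * params.min_step_ms else 2
        other = n + 1 - end_at
        endpoints = [other, end_at] if n_sweeps == 1 else [end_at, other, end_at]
        for i in range(n_sweeps):
            d = full_ms // n_sweeps + (full_ms % n_sweeps if i == n_sweeps - 1 else 0)
            tt, ss = _sweep_events(t, d, endpoints[i], endpoints[i + 1], params.min_step_ms)
            times.append(tt)
            slices.append(ss)
            t += d
        prev_range = (end_at, end_at)  # the sweep's final extremum
    # (ii) oscillation confined to the relevant region, anchored near the
    # current slice so the approach never creates a spurious full run
    if osc_rel_ms > 0:
        a, b = _anchored_range(ivs, prev_range, n)
        tt, ss = _oscillation_events(t, osc_rel_ms, a, b, params.min_step_ms)
        times.append(tt)
        slices.append(ss)
        t += osc_rel_ms
        prev_range = (min(a, b), max(a, b))
    # (iii) remaining dwell on irrelevant slices, last so the trailing state
    # (which persists to question end) is irrelevant
    if irrel_ms > 0:
        a, b = _anchored_range(comp, prev_range, n)
        tt, ss = _oscillation_events(t, irrel_ms, a, b, params.min_step_ms)
        times.append(tt)
        slices.append(ss)
        t += irrel_ms

    if not times:  # zero-length degenerate targets: dwell somewhere
        anchor = comp[0][0] if comp else ivs[0][0]
        times, slices = [np.array([0])], [np.array([anchor])]
    tarr = np.concatenate(times)
    sarr = np.concatenate(slices)
    # enforce strictly increasing integer times (quantization can collide)
    tarr = np.maximum.accumulate(tarr + np.arange(len(tarr)) * 0).astype(int)
    keep = np.ones(len(tarr), dtype=bool)
    keep[1:] = tarr[1:] > tarr[:-1]
    tarr, sarr = tarr[keep], sarr[keep]
    events = [
        ScrollEvent(int(tm), axis, int(sl), "scroll") for tm, sl in zip(tarr, sarr)
    ]
    log = QuestionLog(
        resident_id="sim",
        drpt_id="sim",
        question_id="sim",
        events=events,
        question_end_ms=total,
    ).validate(params.geometry)
    truth = {
        "perc_time_full_runs": f,
        "perc_time_rel_area": r,
        "total_time_ms": total,
        "axis": axis,
    }
    return log, truth


# ---------------------------------------------------------------------------
# macro level: resident x DRPT records
# ---------------------------------------------------------------------------


def simulate_cohort(
    params: CohortParams = CohortParams(), seed: int | np.random.Generator = 0
) -> tuple[list[DRPTRecord], dict]:
    """Draw a synthetic resident x DRPT table from the published models.

    Returns ``(records, truth)``; ``truth`` carries the generating
    parameters, the per-resident random intercepts and the per-DRPT
    difficulty and question counts.  Gaussian outcome draws are left
    untruncated (the generating linear model does not respect percentage
    bounds; truncating would bias slope recovery).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dates = list(params.drpt_dates)
    n_tests = len(dates)
    drpt_ids = [f"D{i + 1}" for i in range(n_tests)]

    diffs = np.clip(
        rng.normal(params.drpt_diff_mean, params.drpt_diff_sd, n_tests),
        *params.drpt_diff_range,
    )
    n_q = rng.binomial(7, 3 / 7, n_tests) + 2  # mean 5, range [2, 9]

    b0f, btf, bdf, s2ef, s2uf = params.fullruns
    b0r, btr, bdr, s2er, s2ur = params.relarea
    b0a, bta, bfa, bra, bda, s2ua = params.accuracy

    window_days = (params.enrolment_end - params.enrolment_start).days
    records: list[DRPTRecord] = []
    residents: dict[str, Resident] = {}
    intercepts: dict[str, tuple[float, float, float]] = {}
    i = 0
    while len(residents) < params.n_residents:
        rid = f"R{i + 1:04d}"
        i += 1
        start = params.enrolment_start + timedelta(days=int(rng.integers(0, window_days)))
        dur = rng.uniform(*params.duration_years_range)
        end = start + timedelta(days=int(round(dur * 365.25)))
        occ = [
            k
            for k, d in enumerate(dates)
            if start < d <= end and rng.random() < params.participation_prob
        ]
        if not occ:
            continue
        res = Resident(rid, start, end)
        residents[rid] = res
        u0f = rng.normal(0, math.sqrt(s2uf))
        u0r = rng.normal(0, math.sqrt(s2ur))
        u0a = rng.normal(0, math.sqrt(s2ua))
        intercepts[rid] = (u0f, u0r, u0a)
        for k in occ:
            t = training_time(dates[k], res)
            d = float(diffs[k])
            yf = b0f + btf * t + bdf * d + u0f + rng.normal(0, math.sqrt(s2ef))
            yr = b0r + btr * t + bdr * d + u0r + rng.normal(0, math.sqrt(s2er))
            p = expit(b0a + bta * t + bfa * yf + bra * yr + bda * d + u0a)
            nq = int(n_q[k])
            records.append(
                DRPTRecord(
                    resident_id=rid,
                    drpt_id=drpt_ids[k],
                    tr_time=t,
                    drpt_diff=d,
                    perc_time_full_runs_avg=float(yf),
                    perc_time_rel_area_avg=float(yr),
                    n_correct=int(rng.binomial(nq, p)),
                    n_questions=nq,
                )
            )
    truth = {
        "params": params,
        "residents": residents,
        "drpt_ids": drpt_ids,
        "drpt_dates": dates,
        "drpt_diffs": {drpt_ids[k]: float(diffs[k]) for k in range(n_tests)},
        "n_questions": {drpt_ids[k]: int(n_q[k]) for k in range(n_tests)},
        "intercepts": intercepts,
    }
    return records, truth


# ---------------------------------------------------------------------------
# micro cohort: logfiles + cohort tables the full pipeline can consume
# ---------------------------------------------------------------------------


@dataclass
class MicroCohort:
    """In-memory fixture: everything the pipeline reads, plus ground truth."""

    residents: dict[str, Resident]
    drpts: dict[str, DRPTInfo]
    questions: dict[str, QuestionInfo]
    answers: pd.DataFrame
    logs: list[QuestionLog]
    truth: dict


def simulate_micro_cohort(
    params: CohortParams = CohortParams(n_residents=20),
    seed: int = 0,
    question_noise_sd: float = 4.0,
    mean_question_time_ms: int = 122_900,
    n_slices: int = 60,
    n_missing_logs: int = 0,
    out_dir=None,
) -> MicroCohort:
    """Compose macro targets with per-question trajectories.

    Each macro record's scroll averages become per-question trajectory
    targets (plus question-level jitter with sd ``question_noise_sd``,
    clipped to the feasible range of the question's relevant region).  Each
    question gets an axial stack of ``n_slices`` slices and one focal
    relevant interval covering 10-35% of the stack.  When ``out_dir`` is
    given, cohort tables and one logfile per resident x question are also
    written there; ``n_missing_logs`` randomly withheld logfiles emulate
    missing data.
    """
    rng = np.random.default_rng(seed)
    records, truth = simulate_cohort(params, seed=rng)
    drpt_ids = truth["drpt_ids"]
    dates = truth["drpt_dates"]

    formats = ["multiple_choice", "long_list", "marker"]
    questions: dict[str, QuestionInfo] = {}
    q_by_drpt: dict[str, list[str]] = {}
    for did in drpt_ids:
        nq = truth["n_questions"][did]
        diff = truth["drpt_diffs"][did]
        jitter = rng.normal(0, 0.05, nq)
        p_vals = np.clip(0.5 + diff + jitter - jitter.mean(), 0.01, 0.99)
        qids = []
        for j in range(nq):
            qid = f"{did}_Q{j + 1}"
            length = int(round(n_slices * rng.uniform(0.10, 0.35)))
            lo = int(rng.integers(1, n_slices - length + 1))
            geometry = VolumeGeometry({"z": n_slices})
            relevant = RelevantRegion({"z": ((lo, lo + length - 1),)})
            fmt = formats[0] if rng.random() < 0.7 else (formats[1] if rng.random() < 0.85 else formats[2])
            questions[qid] = QuestionInfo(
                question_id=qid,
                format=fmt,
                subdomain="synthetic",
                geometry=geometry,
                relevant=relevant,
                p_value=float(p_vals[j]),
            )
            qids.append(qid)
        q_by_drpt[did] = qids

    residents = truth["residents"]
    drpts = {
        did: DRPTInfo(did, dates[k], tuple(q_by_drpt[did]), truth["drpt_diffs"][did])
        for k, did in enumerate(drpt_ids)
    }

    b0a, bta, bfa, bra, bda, _ = params.accuracy
    logs: list[QuestionLog] = []
    answer_rows = []
    for rec in records:
        qids = q_by_drpt[rec.drpt_id]
        u0a = truth["intercepts"][rec.resident_id][2]
        for qid in qids:
            q = questions[qid]
            rel_frac = sum(
                hi - lo + 1 for lo, hi in q.relevant.intervals["z"]
            ) / q.geometry.n_slices["z"]
            f = float(np.clip(rec.perc_time_full_runs_avg + rng.normal(0, question_noise_sd), 0, 95))
            r_lo = f * rel_frac + 0.5
            r_hi = f * rel_frac + (100 - f) - 0.5
            r = float(
                np.clip(rec.perc_time_rel_area_avg + rng.normal(0, question_noise_sd), r_lo, r_hi)
            )
            tp = TrajectoryParams(
                geometry=q.geometry,
                relevant=q.relevant,
                target_perc_full_runs=f,
                target_perc_rel_area=r,
                mean_question_time_ms=int(
                    max(5_000, rng.normal(mean_question_time_ms, mean_question_time_ms / 4))
                ),
                noise_sd=0.0,
            )
            log, _ = simulate_trajectory(tp, seed=rng)
            log = replace_ids(log, rec.resident_id, rec.drpt_id, qid)
            logs.append(log)
            p = expit(
                b0a
                + bta * rec.tr_time
                + bfa * rec.perc_time_full_runs_avg
                + bra * rec.perc_time_rel_area_avg
                + bda * rec.drpt_diff
                + u0a
            )
            answer_rows.append(
                {
                    "resident_id": rec.resident_id,
                    "drpt_id": rec.drpt_id,
                    "question_id": qid,
                    "correct": int(rng.random() < p),
                }
            )
    answers = pd.DataFrame(answer_rows)

    if n_missing_logs:
        drop = rng.choice(len(logs), size=min(n_missing_logs, len(logs)), replace=False)
        keep = np.ones(len(logs), dtype=bool)
        keep[drop] = False
        logs = [lg for lg, k in zip(logs, keep) if k]

    cohort = MicroCohort(
        residents=residents,
        drpts=drpts,
        questions=questions,
        answers=answers,
        logs=logs,
        truth={**truth, "macro_records": records},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_cohort(out_dir, residents, drpts, questions, answers)
        log_dir = out_dir / "logs"
        log_dir.mkdir(parents=True, exist_ok=True)
        for lg in logs:
            write_question_log(
                lg, log_dir / log_filename(lg.resident_id, lg.drpt_id, lg.question_id)
            )
    return cohort


def replace_ids(log: QuestionLog, resident_id: str, drpt_id: str, question_id: str) -> QuestionLog:
    return QuestionLog(resident_id, drpt_id, question_id, log.events, log.question_end_ms)
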