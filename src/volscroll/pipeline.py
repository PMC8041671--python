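"""End-to-end orchestration: parse -> metrics -> aggregate -> fit.

The stages are plain functions over in-memory objects so each is usable and
testable on its own; :func:`run_pipeline` wires them over an on-disk layout
(cohort tables plus a logfile directory) and writes every intermediate as
delimited text, deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import aggregate_to_drpt, select_questions
from .logio import parse_log_filename, read_cohort, read_question_log
from .models import (
    ModelFit,
    fit_binomial_ladder,
    fit_lmm_ladder,
    records_to_frame,
    select_best,
)
from .records import (
    DRPTRecord,
    QuestionInfo,
    QuestionLog,
    QuestionMetrics,
    Resident,
    ValidationError,
)
from .relevance import time_in_relevant_area
from .runs import perc_time_full_runs


@dataclass
class RunConfig:
    """One pipeline run: inputs, selection flags, model options, outputs."""

    tables_dir: Path
    log_dir: Path
    output_dir: Path
    exclude_formats: frozenset[str] = frozenset({"marker"})
    reference_axis: str = "z"
    alpha: float = 0.05
    seed: int = 0
    fit_models: bool = True

    def __post_init__(self) -> None:
        self.tables_dir = Path(self.tables_dir)
        self.log_dir = Path(self.log_dir)
        self.output_dir = Path(self.output_dir)
        for p in (self.tables_dir, self.log_dir):
            if not p.exists():
                raise ValidationError(f"input path {p} does not exist")


def compute_question_metrics(
    logs: list[QuestionLog],
    questions: dict[str, QuestionInfo],
    answers: pd.DataFrame | None = None,
) -> list[QuestionMetrics]:
    """Per-log scroll metrics joined with 0/1 correctness.

    Logs of questions absent from ``questions`` are skipped (they were not
    selected); a missing answer leaves ``correct`` as None (missing
    listwise in the accuracy counts).
    """
    key_to_correct: dict[tuple[str, str, str], int] = {}
    if answers is not None:
        for row in answers.itertuples(index=False):
            key_to_correct[(str(row.resident_id), str(row.drpt_id), str(row.question_id))] = int(
                row.correct
            )
    out: list[QuestionMetrics] = []
    for log in logs:
        q = questions.get(log.question_id)
        if q is None:
            continue
        rp = perc_time_full_runs(log, q.geometry)
        rel = time_in_relevant_area(log, q.relevant)
        out.append(
            QuestionMetrics(
                resident_id=log.resident_id,
                drpt_id=log.drpt_id,
                question_id=log.question_id,
                perc_time_full_runs=rp.perc_time_full_runs,
                perc_time_rel_area=rel.perc_time_rel_area,
                total_time_ms=log.question_end_ms,
                correct=key_to_correct.get(
                    (log.resident_id, log.drpt_id, log.question_id)
                ),
            )
        )
    return out


def metrics_to_frame(metrics: list[QuestionMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "resident_id": [m.resident_id for m in metrics],
            "drpt_id": [m.drpt_id for m in metrics],
            "question_id": [m.question_id for m in metrics],
            "perc_time_full_runs": [m.perc_time_full_runs for m in metrics],
            "perc_time_rel_area": [m.perc_time_rel_area for m in metrics],
            "total_time_ms": [m.total_time_ms for m in metrics],
            "correct": [m.correct for m in metrics],
        }
    )


def fit_report(fit: ModelFit) -> pd.DataFrame:
    rows = [
        {
            "term": fe.name,
            "b": fe.b,
            "se": fe.se,
            "p": fe.p,
            "or": fe.or_,
            "ci_lo": fe.ci[0] if fe.ci else None,
            "ci_hi": fe.ci[1] if fe.ci else None,
        }
        for fe in fit.fixed
    ]
    rows.append({"term": "sigma2_e", "b": fit.var.sigma2_e})
    rows.append({"term": "sigma2_u0", "b": fit.var.sigma2_u0})
    if fit.var.sigma2_u1 is not None:
        rows.append({"term": "sigma2_u1", "b": fit.var.sigma2_u1})
    rows.append({"term": "deviance", "b": fit.deviance})
    if fit.r2_level1 is not None:
        rows.append({"term": "r2_level1", "b": fit.r2_level1})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run parse -> metrics -> aggregate -> fit on an on-disk cohort.

    Writes ``question_metrics.csv``, ``drpt_records.csv``, one
    ``model_<outcome>_<model>.csv`` per ladder rung, and ``run_log.json``
    with versions, seeds and rejection counts.  Returns the bundle as a
    dict.  Any stage failure aborts with a stage-attributed message.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = "parse"
    try:
        residents, drpts, questions, answers = read_cohort(config.tables_dir)
        selection = select_questions(questions.values(), config.reference_axis)
        selected = {q.question_id: q for q in selection.kept}
        logs: list[QuestionLog] = []
        n_skipped = 0
        for path in sorted(config.log_dir.glob("*.log.csv")):
            rid, did, qid = parse_log_filename(path.name)
            q = selected.get(qid)
            if q is None:
                n_skipped += 1
                continue
            logs.append(read_question_log(path, q.geometry, ids=(rid, did, qid)))

        stage = "metrics"
        metrics = compute_question_metrics(logs, selected, answers)
        metrics_to_frame(metrics).to_csv(out / "question_metrics.csv", index=False)

        stage = "aggregate"
        drpt_dates = {d.drpt_id: d.date for d in drpts.values()}
        drpt_diffs = {
            d.drpt_id: _drpt_diff_from_questions(d.drpt_id, metrics, selected)
            for d in drpts.values()
        }
        q_formats = {q.question_id: q.format for q in selected.values()}
        records = aggregate_to_drpt(
            metrics,
            residents,
            drpt_dates,
            drpt_diffs,
            exclude_formats=config.exclude_formats,
            question_formats=q_formats,
        )
        rec_df = records_to_frame(records)
        rec_df.to_csv(out / "drpt_records.csv", index=False)

        fits: dict[str, list[ModelFit]] = {}
        best: dict[str, str] = {}
        if config.fit_models and len(records) >= 4:
            stage = "fit"
            for outcome in ("perc_time_full_runs_avg", "perc_time_rel_area_avg"):
                ladder = fit_lmm_ladder(records, outcome)
                fits[outcome] = ladder
                for f in ladder:
                    fit_report(f).to_csv(
                        out / f"model_{outcome}_{f.name.replace(' ', '').lower()}.csv",
                        index=False,
                    )
                try:
                    best[outcome] = select_best(ladder, config.alpha).name
                except ValidationError:
                    best[outcome] = "none"
            ladder = fit_binomial_ladder(records)
            fits["accuracy"] = ladder
            for f in ladder:
                fit_report(f).to_csv(
                    out / f"model_accuracy_{f.name.replace(' ', '').lower()}.csv",
                    index=False,
                )
            try:
                best["accuracy"] = select_best(ladder, config.alpha).name
            except ValidationError:
                best["accuracy"] = "none"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "n_logs": len(logs),
        "n_logs_skipped_unselected": n_skipped,
        "n_questions_selected": selection.n_kept,
        "rejections": {
            "not_single_ct": selection.rejected_not_single_ct,
            "no_diagnosis": selection.rejected_no_diagnosis,
            "diffuse": selection.rejected_diffuse,
            "flagged": list(selection.flagged),
        },
        "n_records": len(records),
        "best_models": best,
        "exclude_formats": sorted(config.exclude_formats),
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2)
    return {
        "metrics": metrics,
        "records": records,
        "fits": fits,
        "selection": selection,
        "run_log": run_log,
    }


def _drpt_diff_from_questions(
    drpt_id: str, metrics: list[QuestionMetrics], questions: dict[str, QuestionInfo]
) -> float:
    """Mean P value minus 0.5 over the selected questions seen on a test."""
    from .cohort import drpt_difficulty

    qids = sorted({m.question_id for m in metrics if m.drpt_id == drpt_id})
    if not qids:
        warnings.warn(f"DRPT {drpt_id}: no selected questions with logs; difficulty 0")
        return 0.0
    return drpt_difficulty([questions[q].p_value for q in qids])
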