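"""Descriptive outputs: binned trajectories, format-stratified tables and
item-level cross-sectional scatterplots."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import records_to_frame
from .records import DRPTRecord, QuestionMetrics, ValidationError


def binned_descriptives(
    records: Iterable[DRPTRecord] | pd.DataFrame, bin_width_years: float = 0.5
) -> pd.DataFrame:
    """Mean/SD of both averaged scroll metrics per training-time bin.

    Training time stays continuous in every model; the bins exist purely
    for illustration.  Residents appear in every bin they have a test in.
    A single-record bin reports an empty SD.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValidationError("no records to bin")
    edges = np.arange(0.0, 5.0 + bin_width_years, bin_width_years)
    labels = [f"{lo:g}–{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
    df = df.assign(
        bin=pd.cut(df["tr_time"], bins=edges, labels=labels, include_lowest=True, right=False)
    )
    rows = []
    for label, g in df.groupby("bin", observed=True):
        rows.append(
            {
                "tr_time_bin": label,
                "n": len(g),
                "full_runs_mean": g["perc_time_full_runs_avg"].mean(),
                "full_runs_sd": g["perc_time_full_runs_avg"].std() if len(g) > 1 else np.nan,
                "rel_area_mean": g["perc_time_rel_area_avg"].mean(),
                "rel_area_sd": g["perc_time_rel_area_avg"].std() if len(g) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def format_stratified_descriptives(
    metrics: Sequence[QuestionMetrics],
    question_formats: dict[str, str],
) -> pd.DataFrame:
    """Mean/SD of both question-level metrics by format x correctness.

    Empty strata are omitted; the per-stratum counts sum to the number of
    scored input metrics.
    """
    rows = [
        {
            "format": question_formats.get(m.question_id, "unknown"),
            "correct": m.correct,
            "perc_time_full_runs": m.perc_time_full_runs,
            "perc_time_rel_area": m.perc_time_rel_area,
        }
        for m in metrics
        if m.correct is not None
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "format", "correct", "n",
                "rel_area_mean", "rel_area_sd",
                "full_runs_mean", "full_runs_sd",
            ]
        )
    out = []
    for (fmt, corr), g in df.groupby(["format", "correct"]):
        out.append(
            {
                "format": fmt,
                "correct": int(corr),
                "n": len(g),
                "rel_area_mean": g["perc_time_rel_area"].mean(),
                "rel_area_sd": g["perc_time_rel_area"].std() if len(g) > 1 else np.nan,
                "full_runs_mean": g["perc_time_full_runs"].mean(),
                "full_runs_sd": g["perc_time_full_runs"].std() if len(g) > 1 else np.nan,
            }
        )
    return pd.DataFrame(out)


def trend_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """OLS slope of the fitted linear trend line (visual aid, not inference)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least two points for a trend line")
    return float(np.polyfit(x, y, 1)[0])


def item_scatter(
    metrics: Sequence[QuestionMetrics],
    tr_times: dict[tuple[str, str], float],
    outcome: str = "perc_time_full_runs",
    by_correctness: bool = False,
    path=None,
):
    """Cross-sectional scatter of one question-level metric against TrTime,
    with the OLS trend line and its slope (2 decimals) annotated.

    ``tr_times`` maps (resident_id, drpt_id) to relative training time.
    Returns ``(figure, slope)``; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [
        (tr_times[(m.resident_id, m.drpt_id)], getattr(m, outcome), m.correct)
        for m in metrics
        if (m.resident_id, m.drpt_id) in tr_times
    ]
    if len(pts) < 2:
        raise ValidationError("need at least two points to plot")
    x, y, corr = map(np.asarray, zip(*pts))
    slope = trend_slope(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    if by_correctness:
        for val, marker, label in ((1, "o", "correct"), (0, "x", "incorrect")):
            sel = corr == val
            ax.scatter(x[sel], y[sel], s=12, marker=marker, label=label, alpha=0.6)
        ax.legend(frameon=False)
    else:
        ax.scatter(x, y, s=12, alpha=0.6)
    xs = np.array([x.min(), x.max()])
    b, a = np.polyfit(x, y, 1)[0], np.polyfit(x, y, 1)[1]
    ax.plot(xs, b * xs + a, color="k")
    ax.annotate(f"slope = {slope:.2f}", xy=(0.05, 0.92), xycoords="axes fraction")
    ax.set_xlabel("relative training time (years)")
    ax.set_ylabel(outcome)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, slope
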