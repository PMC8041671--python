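"""Run the full pipeline on an on-disk synthetic micro-cohort.

Writes viewer logfiles plus cohort tables for a small cohort, then runs
parse -> metrics -> aggregate -> fit from disk, exactly as one would on
real exported logs.
"""

import json
import tempfile
from pathlib import Path

from volscroll import CohortParams, RunConfig, run_pipeline, simulate_micro_cohort

workdir = Path(tempfile.mkdtemp(prefix="volscroll_"))
data = workdir / "data"

simulate_micro_cohort(
    CohortParams(n_residents=40),
    seed=7,
    mean_question_time_ms=30_000,
    out_dir=data,
)
n_logs = len(list((data / "logs").glob("*.log.csv")))
print(f"wrote synthetic cohort to {data} ({n_logs} logfiles)")

bundle = run_pipeline(
    RunConfig(tables_dir=data, log_dir=data / "logs", output_dir=workdir / "out")
)
print(json.dumps(bundle["run_log"], indent=2))
print()
print("question_metrics.csv holds one row per resident x question;")
print("drpt_records.csv one row per resident x test; model_*.csv the")
print("fitted ladders. best_models names the rung each likelihood-ratio")
print("ladder settled on.")
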