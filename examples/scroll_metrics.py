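"""Segment one CT-stack scroll trajectory and time its relevant-area dwell.

Builds a synthetic 60-slice axial question whose relevant region is slices
20-30, generates a 60-second trajectory that spends ~20% of its time on
full runs (sweeps through more than half the stack) and ~50% displaying
relevant slices, then measures both percentages back from the event stream.
"""

from volscroll import (
    RelevantRegion,
    TrajectoryParams,
    VolumeGeometry,
    perc_time_full_runs,
    simulate_trajectory,
    time_in_relevant_area,
)

geometry = VolumeGeometry({"z": 60})
relevant = RelevantRegion({"z": ((20, 30),)})

params = TrajectoryParams(
    geometry=geometry,
    relevant=relevant,
    target_perc_full_runs=20.0,
    target_perc_rel_area=50.0,
    mean_question_time_ms=60_000,
)
log, truth = simulate_trajectory(params, seed=1)

runs = perc_time_full_runs(log, geometry)
dwell = time_in_relevant_area(log, relevant)

print(f"events in log:            {len(log.events)}")
print(f"question time:            {log.question_end_ms / 1000:.1f} s")
print(f"full runs detected:       {runs.n_full_runs}")
print(f"time on full runs:        {runs.perc_time_full_runs:.1f}%  (target {truth['perc_time_full_runs']:.1f}%)")
print(f"time on relevant slices:  {dwell.perc_time_rel_area:.1f}%  (target {truth['perc_time_rel_area']:.1f}%)")
print()
print("The full-run percentage proxies global (holistic) search: sweeps")
print("covering more than 50% of the slices. The relevant-area percentage")
print("proxies information reduction: dwell on the slices that actually")
print("show the abnormality.")
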