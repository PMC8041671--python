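import numpy as np
import pytest

from volscroll import (
    CohortParams,
    InfeasibleTargetError,
    RelevantRegion,
    TrajectoryParams,
    VolumeGeometry,
    perc_time_full_runs,
    simulate_cohort,
    simulate_micro_cohort,
    simulate_trajectory,
    time_in_relevant_area,
)
from volscroll.models import records_to_frame


@pytest.fixture
def geom():
    return VolumeGeometry({"z": 60})


def params(geom, f, r, iv=(20, 30), **kw):
    return TrajectoryParams(
        geometry=geom,
        relevant=RelevantRegion({"z": (iv,)}),
        target_perc_full_runs=f,
        target_perc_rel_area=r,
        mean_question_time_ms=kw.pop("time_ms", 60_000),
        **kw,
    )


class TestSimulateTrajectory:
    def test_generated_log_passes_validation(self, geom):
        log, _ = simulate_trajectory(params(geom, 20, 50), seed=1)
        assert log.validate(geom) is log

    @pytest.mark.parametrize("f,r,iv", [(20, 50, (20, 30)), (5, 10, (1, 6)),
                                        (60, 30, (50, 59)), (0, 100, (1, 60))])
    def test_pipeline_recovers_targets_at_zero_noise(self, geom, f, r, iv):
        p = params(geom, f, r, iv=iv)
        log, truth = simulate_trajectory(p, seed=2)
        rel = RelevantRegion({"z": (iv,)})
        got_f = perc_time_full_runs(log, geom).perc_time_full_runs
        got_r = time_in_relevant_area(log, rel).perc_time_rel_area
        assert got_f == pytest.approx(truth["perc_time_full_runs"], abs=2.0)
        assert got_r == pytest.approx(truth["perc_time_rel_area"], abs=2.0)

    def test_whole_stack_relevant_recovers_100_100_structure(self, geom):
        # all slices relevant: any mix of sweeping and dwell gives 100% dwell
        p = params(geom, 100, 100, iv=(1, 60))
        log, truth = simulate_trajectory(p, seed=3)
        rel = RelevantRegion({"z": ((1, 60),)})
        assert time_in_relevant_area(log, rel).perc_time_rel_area == pytest.approx(100.0)
        assert perc_time_full_runs(log, geom).perc_time_full_runs == pytest.approx(100.0, abs=2.0)

    def test_infeasible_pair_raises(self, geom):
        # 100% full runs but 100% relevance on a sub-half region is impossible
        with pytest.raises(InfeasibleTargetError):
            simulate_trajectory(params(geom, 100, 100, iv=(20, 30)), seed=1)

    def test_seed_fixed_call_is_reproducible(self, geom):
        a, _ = simulate_trajectory(params(geom, 20, 50, noise_sd=3.0), seed=9)
        b, _ = simulate_trajectory(params(geom, 20, 50, noise_sd=3.0), seed=9)
        assert a.events == b.events

    def test_discrepancy_shrinks_with_noise(self, geom):
        rng_err = []
        for sd in (8.0, 0.0):
            errs = []
            for seed in range(8):
                log, truth = simulate_trajectory(params(geom, 25, 45, noise_sd=sd), seed=seed)
                got = perc_time_full_runs(log, geom).perc_time_full_runs
                errs.append(abs(got - 25.0))
            rng_err.append(np.mean(errs))
        assert rng_err[1] <= rng_err[0]


class TestSimulateCohort:
    def test_zero_variance_zero_slopes_constant_outcomes(self):
        p = CohortParams(
            n_residents=30,
            fullruns=(20.0, 0.0, 0.0, 0.0, 0.0),
            relarea=(50.0, 0.0, 0.0, 0.0, 0.0),
        )
        records, _ = simulate_cohort(p, seed=1)
        assert {r.perc_time_full_runs_avg for r in records} == {20.0}
        assert {r.perc_time_rel_area_avg for r in records} == {50.0}

    def test_panel_structure_matches_study_conditions(self):
        records, truth = simulate_cohort(CohortParams(n_residents=400), seed=6)
        df = records_to_frame(records)
        per_res = df.groupby("resident_id").size()
        assert per_res.min() >= 1 and per_res.max() <= 9
        assert 3.5 <= per_res.mean() <= 4.7
        assert df["tr_time"].between(0, 5).all()
        assert df["drpt_diff"].between(0.02, 0.24).all()
        nq = df.groupby("drpt_id")["n_questions"].first()
        assert nq.between(2, 9).all()

    def test_tr_time_increases_within_resident(self):
        records, _ = simulate_cohort(CohortParams(n_residents=50), seed=2)
        df = records_to_frame(records).sort_values(["resident_id", "drpt_id"])
        for _, g in df.groupby("resident_id"):
            t = g["tr_time"].to_numpy()
            assert (np.diff(t) > 0).all()

    def test_binned_means_trend_in_generating_directions(self):
        from volscroll import binned_descriptives

        records, _ = simulate_cohort(CohortParams(n_residents=650), seed=4)
        table = binned_descriptives(records, bin_width_years=1.0)
        fr = table["full_runs_mean"].to_numpy()
        ra = table["rel_area_mean"].to_numpy()
        # qualitative trend over five years of training
        assert fr[-1] < fr[0]
        assert ra[-1] > ra[0]


class TestSimulateMicroCohort:
    def test_tiny_fixture_builds_and_validates(self):
        mc = simulate_micro_cohort(
            CohortParams(n_residents=5), seed=1, mean_question_time_ms=20_000
        )
        assert len(mc.logs) > 0
        for log in mc.logs[:20]:
            q = mc.questions[log.question_id]
            assert log.validate(q.geometry) is log

    def test_on_disk_fixture_round_trips_through_pipeline(self, tmp_path):
        from volscroll import RunConfig, run_pipeline

        simulate_micro_cohort(
            CohortParams(n_residents=6), seed=2,
            mean_question_time_ms=20_000, out_dir=tmp_path,
        )
        out = tmp_path / "out"
        bundle = run_pipeline(
            RunConfig(tables_dir=tmp_path, log_dir=tmp_path / "logs",
                      output_dir=out, fit_models=False)
        )
        assert (out / "question_metrics.csv").exists()
        assert (out / "drpt_records.csv").exists()
        assert bundle["run_log"]["n_records"] == len(bundle["records"])

    def test_missing_logfiles_leave_aggregation_functional(self):
        from volscroll.cohort import aggregate_to_drpt
        from volscroll.pipeline import compute_question_metrics

        mc = simulate_micro_cohort(
            CohortParams(n_residents=8), seed=3,
            mean_question_time_ms=20_000, n_missing_logs=9,
        )
        metrics = compute_question_metrics(mc.logs, mc.questions, mc.answers)
        recs = aggregate_to_drpt(
            metrics,
            mc.residents,
            {d.drpt_id: d.date for d in mc.drpts.values()},
            {d.drpt_id: d.drpt_diff for d in mc.drpts.values()},
        )
        assert len(recs) > 0

    def test_measured_averages_track_macro_targets(self):
        from volscroll.cohort import aggregate_to_drpt
        from volscroll.pipeline import compute_question_metrics

        mc = simulate_micro_cohort(
            CohortParams(n_residents=25), seed=4,
            question_noise_sd=2.0, mean_question_time_ms=20_000,
        )
        metrics = compute_question_metrics(mc.logs, mc.questions, mc.answers)
        recs = aggregate_to_drpt(
            metrics,
            mc.residents,
            {d.drpt_id: d.date for d in mc.drpts.values()},
            {d.drpt_id: d.drpt_diff for d in mc.drpts.values()},
        )
        macro = {(r.resident_id, r.drpt_id): r for r in mc.truth["macro_records"]}
        diffs = [
            r.perc_time_full_runs_avg - macro[(r.resident_id, r.drpt_id)].perc_time_full_runs_avg
            for r in recs
        ]
        assert abs(np.mean(diffs)) < 1.5
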