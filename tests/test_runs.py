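import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from volscroll import (
    ScrollEvent,
    UndefinedMetricError,
    VolumeGeometry,
    axis_episodes,
    find_extrema,
    perc_time_full_runs,
    segment_runs,
)

from .conftest import brute_force_runs, make_log, random_log


class TestAxisEpisodes:
    def test_single_axis_log_is_one_episode(self):
        log = make_log([(0, 10), (500, 20), (900, 30)], end_ms=2000)
        eps = axis_episodes(log)
        assert len(eps) == 1
        assert eps[0].axis == "z"
        assert (eps[0].t_start_ms, eps[0].t_end_ms) == (0, 2000)

    def test_axis_changes_split_episodes(self):
        log = make_log(
            [(0, "z", 10), (500, "x", 5), (900, "z", 30)], end_ms=2000
        )
        eps = axis_episodes(log)
        assert [e.axis for e in eps] == ["z", "x", "z"]

    def test_episode_spans_partition_question_time(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            log = random_log(rng, axes=("x", "y", "z"))
            eps = axis_episodes(log)
            assert eps[0].t_start_ms == 0
            assert eps[-1].t_end_ms == log.question_end_ms
            for a, b in zip(eps[:-1], eps[1:]):
                assert a.t_end_ms == b.t_start_ms


class TestFindExtrema:
    @pytest.mark.parametrize(
        "slices, expected",
        [
            ([10, 20, 30], [10, 30]),  # monotone sweep
            ([10, 80, 20], [10, 80, 20]),  # single reversal each side
            ([5, 5, 5], [5]),  # stationary episode
            ([10, 20, 20, 30, 25], [10, 30, 25]),  # plateau is no extremum
        ],
    )
    def test_reversal_detection(self, slices, expected):
        log = make_log([(i * 100, s) for i, s in enumerate(slices)])
        (ep,) = axis_episodes(log)
        assert [s for _, s in find_extrema(ep)] == expected

    def test_plateau_keeps_first_timestamp(self):
        log = make_log([(0, 10), (100, 50), (200, 50), (300, 10)])
        (ep,) = axis_episodes(log)
        assert find_extrema(ep)[1] == (100, 50)


class TestSegmentRuns:
    def test_single_full_sweep(self):
        log = make_log([(i * 40, s) for i, s in enumerate(range(1, 101))])
        (ep,) = axis_episodes(log)
        runs = [r for r in segment_runs(ep, 100) if r.delta_slices > 0]
        assert len(runs) == 1
        assert runs[0].delta_slices == 99
        assert runs[0].is_full
        assert runs[0].duration_ms == 99 * 40

    def test_two_reversal_trajectory(self):
        # extrema at 10 (t=0), 80 (t=2000), 20 (t=3000): both spans full
        log = make_log([(0, 10), (1000, 45), (2000, 80), (3000, 20)])
        (ep,) = axis_episodes(log)
        runs = segment_runs(ep, 100)
        assert [(r.slice_start, r.slice_end, r.is_full) for r in runs] == [
            (10, 80, True),
            (80, 20, True),
        ]
        assert [r.duration_ms for r in runs] == [2000, 1000]

    def test_small_oscillation_never_full(self):
        pts = [(i * 100, 40 if i % 2 == 0 else 45) for i in range(20)]
        log = make_log(pts)
        (ep,) = axis_episodes(log)
        assert not any(r.is_full for r in segment_runs(ep, 100))

    def test_exact_half_span_is_not_full(self):
        # delta = 50 of 100 slices: "more than 50%" is strict
        log = make_log([(0, 25), (1000, 75)])
        (ep,) = axis_episodes(log)
        (run,) = segment_runs(ep, 100)
        assert run.delta_slices == 50
        assert not run.is_full

    def test_one_more_slice_is_full(self):
        log = make_log([(0, 25), (1000, 76)])
        (ep,) = axis_episodes(log)
        (run,) = segment_runs(ep, 100)
        assert run.is_full


class TestPercTimeFullRuns:
    def test_full_sweep_entire_question_is_100(self):
        log = make_log([(i * 10, s) for i, s in enumerate(range(1, 101))], end_ms=990)
        profile = perc_time_full_runs(log, VolumeGeometry({"z": 100}))
        assert profile.perc_time_full_runs == pytest.approx(100.0)

    def test_no_full_runs_is_0(self):
        log = make_log([(0, 40), (500, 45), (1000, 40)], end_ms=2000)
        profile = perc_time_full_runs(log, VolumeGeometry({"z": 100}))
        assert profile.perc_time_full_runs == 0.0

    def test_quarter_time_sweep_is_25_percent(self):
        # sweep 1->100 over 1000 ms, then stationary until 4000 ms
        pts = [(round(i * 1000 / 99), s) for i, s in enumerate(range(1, 101))]
        log = make_log(pts, end_ms=4000)
        profile = perc_time_full_runs(log, VolumeGeometry({"z": 100}))
        assert profile.perc_time_full_runs == pytest.approx(25.0, abs=0.01)

    def test_zero_total_time_is_undefined(self):
        log = make_log([(0, 10)], end_ms=0)
        with pytest.raises(UndefinedMetricError):
            perc_time_full_runs(log, VolumeGeometry({"z": 100}))


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_trajectories(self):
        rng = np.random.default_rng(1234)
        n_slices = 30
        geom = VolumeGeometry({"z": n_slices})
        for _ in range(1000):
            log = random_log(rng, n_slices=n_slices, max_events=50)
            profile = perc_time_full_runs(log, geom)
            (ep,) = axis_episodes(log)
            ref = brute_force_runs(
                [ev.time_ms for ev in log.display_events],
                [ev.slice_index for ev in log.display_events],
                n_slices,
                log.question_end_ms,
            )
            got = [
                (r.t_start_ms, r.t_end_ms, r.delta_slices, r.is_full)
                for r in profile.runs
            ]
            assert got == ref

    def test_full_time_matches_brute_force_sum(self):
        rng = np.random.default_rng(99)
        geom = VolumeGeometry({"z": 30})
        for _ in range(200):
            log = random_log(rng, n_slices=30)
            profile = perc_time_full_runs(log, geom)
            ref = brute_force_runs(
                [ev.time_ms for ev in log.display_events],
                [ev.slice_index for ev in log.display_events],
                30,
                log.question_end_ms,
            )
            assert profile.full_run_time_ms == sum(
                t1 - t0 for t0, t1, _, full in ref if full
            )


class TestInvariants:
    def test_run_durations_tile_question_time(self):
        rng = np.random.default_rng(7)
        geom = VolumeGeometry({"x": 40, "y": 50, "z": 100})
        for _ in range(100):
            log = random_log(rng, n_slices=40, axes=("x", "y", "z"))
            total = sum(
                r.duration_ms
                for ep in axis_episodes(log)
                for r in segment_runs(ep, geom.n_slices[ep.axis])
            )
            assert total == log.question_end_ms

    def test_adding_mid_question_sweep_never_decreases_metric(self):
        geom = VolumeGeometry({"z": 100})
        base = make_log([(0, 40), (2000, 45), (4000, 40)], end_ms=6000)
        before = perc_time_full_runs(base, geom).perc_time_full_runs
        widened = make_log(
            [(0, 40), (2000, 45), (3000, 1), (4000, 100), (5000, 40)], end_ms=6000
        )
        after = perc_time_full_runs(widened, geom).perc_time_full_runs
        assert after >= before

    @given(scale=st.integers(min_value=2, max_value=20))
    @settings(deadline=None)
    def test_time_scale_equivariance(self, scale):
        geom = VolumeGeometry({"z": 100})
        pts = [(0, 10), (400, 90), (700, 30), (1100, 35)]
        base = make_log(pts, end_ms=1500)
        scaled = make_log([(t * scale, s) for t, s in pts], end_ms=1500 * scale)
        assert perc_time_full_runs(base, geom).perc_time_full_runs == pytest.approx(
            perc_time_full_runs(scaled, geom).perc_time_full_runs
        )

    def test_pan_zoom_events_never_change_metric(self):
        rng = np.random.default_rng(5)
        geom = VolumeGeometry({"z": 30})
        for _ in range(50):
            log = random_log(rng, n_slices=30)
            base = perc_time_full_runs(log, geom).perc_time_full_runs
            polluted = list(log.events)
            for t in rng.integers(0, log.question_end_ms + 1, size=5):
                polluted.append(ScrollEvent(int(t), None, None, "other"))
            polluted.sort(key=lambda ev: ev.time_ms)
            noisy = type(log)(
                log.resident_id, log.drpt_id, log.question_id, polluted, log.question_end_ms
            )
            assert perc_time_full_runs(noisy, geom).perc_time_full_runs == base
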