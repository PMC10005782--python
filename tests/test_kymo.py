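"""Tests for kymograph construction, tip extraction, segmentation and
lifetime grouping."""

import dataclasses

import numpy as np
import pytest

from conftest import make_three_phase_trace
from mtkymo import kymo, model
from mtkymo.kymo import (
    LifetimeRecord,
    PhaseSegment,
    SegConfig,
    TipDetectConfig,
    Trace,
    TraceError,
    build_kymograph,
    extract_tip_trace,
    lifetimes_from_truth,
    segment_trace,
    split_lifetimes,
    trace_from_trajectory,
)


class TestBuildKymograph:
    def test_frame_indexed_stack_gives_constant_rows(self):
        stack = np.ones((5, 20, 20)) * np.arange(5)[:, None, None]
        out = build_kymograph(stack, [(10.0, 2.0), (10.0, 15.0)], width=1)
        raster = out.channels["lattice"]
        for t in range(5):
            np.testing.assert_allclose(raster[t], t)

    def test_uniform_stack_invariant_to_width(self):
        stack = np.full((3, 30, 30), 7.5)
        out = build_kymograph(stack, [(5.0, 5.0), (20.0, 20.0), (20.0, 28.0)], width=3)
        np.testing.assert_allclose(out.channels["lattice"], 7.5)

    def test_vertex_outside_frame_errors(self):
        stack = np.zeros((2, 10, 10))
        with pytest.raises(Exception):
            build_kymograph(stack, [(5.0, 5.0), (5.0, 30.0)], width=1)

    def test_empty_stack_errors(self):
        with pytest.raises(TraceError):
            build_kymograph(np.zeros((0, 5, 5)), [(1, 1), (1, 3)])


class TestExtractTipTrace:
    def test_noiseless_positions_within_one_pixel_of_truth(self):
        trajs = model.simulate_condition(model.PIPELINE_VALIDATION_PARAMS, 5,
                                         900.0, master_seed=13)
        for traj in trajs:
            img = model.render_kymograph(traj, model.fit_roi(traj), rng_seed=0)
            trace = extract_tip_trace(img)
            px = traj.calibration.pixel_size
            visible = traj.lengths > 4 * px  # above the optical blind zone
            err = np.abs(trace.positions - traj.lengths)[visible]
            assert np.nanmax(err) <= px

    def test_all_background_lattice_yields_missing_with_warning(self):
        traj = model.simulate_condition(model.BASELINE_PARAMS, 1, 300.0, master_seed=2)[0]
        img = model.render_kymograph(traj, model.fit_roi(traj), rng_seed=0)
        img.channels["lattice"] = np.full_like(
            img.channels["lattice"], 20.0
        ) + np.random.default_rng(0).normal(0, 1.0, img.channels["lattice"].shape)
        with pytest.warns(UserWarning):
            trace = extract_tip_trace(img, TipDetectConfig(bare_as_zero=False))
        assert np.isnan(trace.positions).all()
        assert trace.n_undetected == trace.positions.size

    def test_growth_slope_recovered_within_5pct_at_snr_10(self):
        p = model.DynamicsParameters(v_g=1.2, v_s=1.0)
        path = model.StatePath(episodes=[("G", 0.0, 900.0)], total_duration=900.0)
        traj = model.path_to_trajectory(path, p)
        optics = model.fit_roi(traj, model.OpticsConfig(noise_sigma=10.0))
        for seed in range(5):
            img = model.render_kymograph(traj, optics, rng_seed=seed)
            trace = extract_tip_trace(img)
            t = trace.frame_times
            slope = np.polyfit(t[20:], trace.positions[20:], 1)[0] * 60.0
            assert slope == pytest.approx(1.2, rel=0.05)

    def test_seed_band_required(self):
        traj = model.simulate_condition(model.BASELINE_PARAMS, 1, 300.0, master_seed=2)[0]
        img = model.render_kymograph(traj, model.fit_roi(traj), rng_seed=0)
        img.channels["seed"] = np.full_like(img.channels["seed"], 20.0)
        with pytest.raises(TraceError):
            extract_tip_trace(img)


class TestSegmentTrace:
    def test_three_phase_noiseless_exact_recovery(self):
        trace = make_three_phase_trace()
        segs = segment_trace(trace)
        assert [s.state for s in segs] == ["growth", "pause", "shrink"]
        assert segs[0].slope == pytest.approx(1.0, abs=1e-9)
        assert segs[1].slope == pytest.approx(0.0, abs=1e-9)
        assert segs[2].slope == pytest.approx(-10.0, abs=1e-9)
        # boundaries at the exact corners (60 s and 90 s)
        assert segs[0].t_end == pytest.approx(60.0, abs=3.0)
        assert segs[1].t_end == pytest.approx(90.0, abs=3.0)

    def test_constant_trace_is_single_pause(self):
        times = np.arange(0, 120, 3.0)
        trace = Trace(frame_times=times, positions=np.full(times.size, 2.0))
        segs = segment_trace(trace)
        assert len(segs) == 1
        assert segs[0].state == "pause"
        assert segs[0].t_start == 0.0 and segs[0].t_end == times[-1]

    def test_three_phase_with_noise_boundaries_within_two_frames(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            trace = make_three_phase_trace(t_grow=90.0, t_pause=45.0,
                                           noise_sd=0.05, rng=rng)
            segs = segment_trace(trace)
            states = [s.state for s in segs]
            if states == ["growth", "pause", "shrink"] and \
                    abs(segs[0].t_end - 90.0) <= 6.0 and abs(segs[1].t_end - 135.0) <= 6.0:
                hits += 1
        assert hits >= 33  # structure and boundaries recovered for most seeds

    def test_segments_partition_trace(self, baseline_condition):
        for traj in baseline_condition[:10]:
            trace = trace_from_trajectory(traj)
            segs = segment_trace(trace)
            assert segs[0].t_start == trace.frame_times[0]
            for a, b in zip(segs, segs[1:]):
                assert a.t_end == pytest.approx(b.t_start, abs=1e-9)
            assert segs[-1].t_end == pytest.approx(trace.frame_times[-1], abs=1e-9)

    def test_raising_pause_threshold_never_decreases_pause_time(self):
        rng = np.random.default_rng(3)
        trace = make_three_phase_trace(t_grow=120.0, t_pause=60.0, noise_sd=0.03, rng=rng)
        prev = -1.0
        for thr in (0.05, 0.15, 0.25, 0.5, 0.9):
            segs = segment_trace(trace, SegConfig(pause_speed_threshold=thr))
            t_pause = sum(s.duration for s in segs if s.state == "pause")
            assert t_pause >= prev - 1e-9
            prev = t_pause

    def test_short_gap_bridged_long_gap_splits(self):
        times = np.arange(0, 300, 3.0)
        pos = times / 60.0 * 1.2
        pos_short = pos.copy()
        pos_short[40:42] = np.nan  # 2-frame dropout: bridged
        segs = segment_trace(Trace(frame_times=times, positions=pos_short))
        assert len(segs) == 1 and segs[0].state == "growth"
        pos_long = pos.copy()
        pos_long[40:50] = np.nan  # 10-frame gap: split
        segs = segment_trace(Trace(frame_times=times, positions=pos_long))
        assert len(segs) == 2
        assert all(s.state == "growth" for s in segs)

    def test_too_short_trace_rejected(self):
        with pytest.raises(TraceError):
            segment_trace(Trace(frame_times=np.arange(4) * 3.0, positions=np.zeros(4)))

    def test_subframe_shrink_dip_recovered_as_catastrophe_rescue(self):
        # growth with a single-frame 0.5 um drop, then continued growth
        times = np.arange(0, 300, 3.0)
        pos = times / 60.0 * 1.2
        pos[50:] -= 0.5
        pos = np.clip(pos, 0, None)
        segs = segment_trace(Trace(frame_times=times, positions=pos))
        assert [s.state for s in segs] == ["growth", "shrink", "growth"]
        assert segs[1].duration <= 6.0

    def test_merged_pause_recovered_by_changepoint_search(self):
        # a 4-frame pause inside growth, below the velocity-run floor once
        # noise fragments it
        rng = np.random.default_rng(5)
        times = np.arange(0, 360, 3.0)
        pos = np.empty(times.size)
        t_p0, t_p1 = 180.0, 192.0
        for i, t in enumerate(times):
            if t < t_p0:
                pos[i] = t / 60 * 1.2
            elif t < t_p1:
                pos[i] = t_p0 / 60 * 1.2
            else:
                pos[i] = t_p0 / 60 * 1.2 + (t - t_p1) / 60 * 1.2
        pos += rng.normal(0, 0.025, pos.size)
        segs = segment_trace(Trace(frame_times=times, positions=np.clip(pos, 0, None)))
        pauses = [s for s in segs if s.state == "pause"]
        assert len(pauses) == 1
        assert pauses[0].t_start == pytest.approx(t_p0, abs=6.0)
        # two-changepoint localization is ~1-2 frames per boundary at this noise
        assert pauses[0].duration == pytest.approx(12.0, abs=9.0)


class TestSplitLifetimes:
    def _segments(self, trace, cfg=None):
        return segment_trace(trace, cfg or SegConfig())

    def test_shrink_to_seed_closes_record(self):
        trace = make_three_phase_trace(t_grow=120.0)
        recs = split_lifetimes(self._segments(trace), trace)
        assert len(recs) == 1
        assert not recs[0].censored
        assert recs[0].segments[0].state == "growth"
        assert recs[0].segments[-1].state == "shrink"

    def test_trace_ending_mid_growth_is_censored(self):
        times = np.arange(0, 300, 3.0)
        trace = Trace(frame_times=times, positions=times / 60.0 * 1.2)
        recs = split_lifetimes(self._segments(trace), trace)
        assert len(recs) == 1 and recs[0].censored

    def test_two_lifetimes_with_bare_gap(self):
        # growth -> shrink to seed -> bare -> growth -> movie end
        times = np.arange(0, 400, 3.0)
        pos = np.zeros(times.size)
        for i, t in enumerate(times):
            if t <= 120:
                pos[i] = t / 60 * 1.2
            elif t <= 150:
                pos[i] = max(2.4 - (t - 120) / 60 * 6.0, 0.0)
            elif t <= 240:
                pos[i] = 0.0
            else:
                pos[i] = (t - 240) / 60 * 1.2
        trace = Trace(frame_times=times, positions=pos)
        recs = split_lifetimes(self._segments(trace), trace)
        assert [r.censored for r in recs] == [False, True]

    def test_subthreshold_excursions_do_not_open_lifetimes(self):
        times = np.arange(0, 120, 3.0)
        pos = np.minimum(times / 60.0 * 0.3, 0.3)  # peak 0.3 um < min_excursion
        trace = Trace(frame_times=times, positions=pos)
        recs = split_lifetimes(self._segments(trace), trace)
        assert recs == []

    def test_records_validate(self, baseline_condition):
        for traj in baseline_condition[:10]:
            trace = trace_from_trajectory(traj)
            for rec in split_lifetimes(self._segments(trace), trace):
                rec.validate()


class TestLifetimesFromTruth:
    def test_counts_against_episode_structure(self):
        p = model.BASELINE_PARAMS
        path = model.sample_state_path(p, 2400.0, rng_seed=17)
        recs = lifetimes_from_truth(path, p)
        n_bare = sum(1 for s, *_ in path.episodes if s == "BARE")
        # one closure per BARE entry; final record censored iff path ends mid-life
        closed = sum(1 for r in recs if not r.censored)
        assert closed == n_bare
        for rec in recs:
            rec.validate()

    def test_truth_route_times_tile_lifetimes(self):
        p = model.BASELINE_PARAMS
        path = model.sample_state_path(p, 2400.0, rng_seed=19)
        for rec in lifetimes_from_truth(path, p):
            total = sum(s.duration for s in rec.segments)
            assert total == pytest.approx(rec.t_end - rec.t_nucleation, abs=1e-6)


class TestConfigValidation:
    def test_min_segment_frames_floor(self):
        with pytest.raises(TraceError):
            SegConfig(min_segment_frames=1)

    def test_negative_threshold_rejected(self):
        with pytest.raises(TraceError):
            SegConfig(pause_speed_threshold=-0.1)

    def test_segment_invariants(self):
        with pytest.raises(TraceError):
            PhaseSegment(state="growth", t_start=10.0, t_end=10.0, slope=1.0)
        with pytest.raises(TraceError):
            PhaseSegment(state="wobble", t_start=0.0, t_end=1.0, slope=0.0)
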