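"""Unit and property tests for the dynamic-instability simulator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtkymo import model
from mtkymo.model import (
    BARE,
    GROWTH,
    SHRINK,
    Calibration,
    DynamicsParameters,
    ModelError,
    OpticsConfig,
)

# fast two-state chain (no pause) whose stationary behavior is known in
# closed form: pi_G = k_sg / (k_sg + k_gs) = 0.8
TWO_STATE = DynamicsParameters(v_g=1.0, v_s=0.0, k_gs=0.5, k_sg=2.0, k_nuc=1.0)


class TestParameterValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ModelError):
            DynamicsParameters(v_g=1.0, v_s=1.0, k_gs=-0.1)

    def test_nucleation_rate_must_be_positive(self):
        with pytest.raises(ModelError):
            DynamicsParameters(v_g=1.0, v_s=1.0, k_nuc=0.0)

    def test_inescapable_shrink_state_rejected(self):
        # shrinkage reachable but v_s = 0 and no exit: time could not advance
        with pytest.raises(ModelError):
            DynamicsParameters(v_g=1.0, v_s=0.0, k_gs=0.5)

    def test_pure_growth_degenerate_model_is_valid(self):
        p = DynamicsParameters(v_g=1.0, v_s=1.0)
        assert p.exit_rate(GROWTH) == 0.0

    def test_calibration_positive(self):
        with pytest.raises(ModelError):
            Calibration(frame_interval=0.0)


class TestSampleStatePath:
    def test_no_transitions_yields_single_growth_episode(self):
        p = DynamicsParameters(v_g=1.0, v_s=1.0)
        path = model.sample_state_path(p, 600.0, rng_seed=0)
        assert path.episodes == [(GROWTH, 0.0, 600.0)]

    def test_reproducible_for_fixed_seed(self):
        a = model.sample_state_path(model.BASELINE_PARAMS, 1200.0, rng_seed=42)
        b = model.sample_state_path(model.BASELINE_PARAMS, 1200.0, rng_seed=42)
        assert a.episodes == b.episodes

    def test_two_state_occupancy_matches_stationary_solution(self):
        # long-run fraction of time growing vs pi_G = 0.8
        path = model.sample_state_path(TWO_STATE, 2e4 * 60.0, rng_seed=1)
        times = path.state_times()
        frac_g = times[GROWTH] / (times[GROWTH] + times[SHRINK])
        assert frac_g == pytest.approx(0.8, rel=0.02)

    def test_exponential_exit_rate_identity(self):
        # catastrophes per minute of growth approaches k_gs
        path = model.sample_state_path(TWO_STATE, 2e4 * 60.0, rng_seed=2)
        n_gs = path.transition_counts().get((GROWTH, SHRINK), 0)
        t_g_min = path.state_times()[GROWTH] / 60.0
        assert n_gs / t_g_min == pytest.approx(0.5, rel=0.03)

    def test_bare_entered_only_at_seed_and_exits_to_growth(self):
        path = model.sample_state_path(model.BASELINE_PARAMS, 3600.0, rng_seed=3)
        eps = path.episodes
        for k, (state, t0, t1) in enumerate(eps):
            if state == BARE:
                if k > 0:
                    assert eps[k - 1][0] == SHRINK
                    length_at = model.path_lengths(path, model.BASELINE_PARAMS,
                                                   np.array([t0]))[0]
                    assert length_at == pytest.approx(0.0, abs=1e-9)
                if k + 1 < len(eps):
                    assert eps[k + 1][0] == GROWTH

    def test_duration_must_be_positive(self):
        with pytest.raises(ModelError):
            model.sample_state_path(TWO_STATE, 0.0, rng_seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        k_gs=st.floats(0.0, 3.0), k_gp=st.floats(0.0, 3.0),
        k_pg=st.floats(0.1, 5.0), k_ps=st.floats(0.0, 2.0),
        k_sg=st.floats(0.1, 5.0), k_sp=st.floats(0.0, 2.0),
        seed=st.integers(0, 2**20),
    )
    def test_episodes_always_tile_duration(self, k_gs, k_gp, k_pg, k_ps, k_sg, k_sp, seed):
        p = DynamicsParameters(v_g=1.0, v_s=8.0, k_gs=k_gs, k_gp=k_gp,
                               k_pg=k_pg, k_ps=k_ps, k_sg=k_sg, k_sp=k_sp, k_nuc=2.0)
        path = model.sample_state_path(p, 900.0, rng_seed=seed)
        path.validate()  # tiling and episode sanity
        total = sum(t1 - t0 for _, t0, t1 in path.episodes)
        assert total == pytest.approx(900.0, abs=1e-6)


class TestPathToTrajectory:
    def test_linear_integration_of_pure_growth(self):
        p = DynamicsParameters(v_g=1.0, v_s=1.0)
        path = model.StatePath(episodes=[(GROWTH, 0.0, 60.0)], total_duration=60.0)
        traj = model.path_to_trajectory(path, p, Calibration(frame_interval=3.0))
        np.testing.assert_allclose(traj.lengths, np.arange(21) * 0.05, atol=1e-12)

    def test_lengths_nonnegative_and_zero_during_bare(self):
        trajs = model.simulate_condition(model.BASELINE_PARAMS, 10, 1200.0, master_seed=7)
        for traj in trajs:
            assert np.all(traj.lengths >= 0)
            for state, t0, t1 in traj.truth.episodes:
                if state == BARE:
                    inside = (traj.frame_times > t0 + 1e-9) & (traj.frame_times < t1 - 1e-9)
                    assert np.all(traj.lengths[inside] == 0.0)

    def test_finite_differences_match_state_speed_within_episodes(self, baseline_condition):
        p = model.BASELINE_PARAMS
        speed = {GROWTH: p.v_g, SHRINK: -p.v_s, "P": 0.0, BARE: 0.0}
        traj = baseline_condition[0]
        dt = traj.calibration.frame_interval
        for state, t0, t1 in traj.truth.episodes:
            # frames strictly interior to the episode
            i = np.nonzero((traj.frame_times >= t0 - 1e-9) & (traj.frame_times + dt <= t1 + 1e-9))[0]
            i = i[:-1]
            if i.size < 1:
                continue
            v = np.diff(traj.lengths)[i] / dt * 60.0
            np.testing.assert_allclose(v, speed[state], atol=1e-9)

    def test_length_conservation_over_full_path(self):
        p = model.BASELINE_PARAMS
        path = model.sample_state_path(p, 1200.0, rng_seed=11)
        traj = model.path_to_trajectory(path, p)
        final = model.path_lengths(path, p, np.array([path.total_duration]))[0]
        assert traj.lengths[-1] == pytest.approx(final, abs=1e-9)


class TestRenderKymograph:
    def test_noiseless_tip_column_advance_matches_pixel_rounding(self):
        p = DynamicsParameters(v_g=1.2, v_s=1.0, seed_length=1.0)
        path = model.StatePath(episodes=[(GROWTH, 0.0, 300.0)], total_duration=300.0)
        traj = model.path_to_trajectory(path, p)
        optics = OpticsConfig(psf_sigma=0.0, noise_sigma=0.0, roi_length=128)
        kymo = model.render_kymograph(traj, optics, rng_seed=0)
        lattice = kymo.channels["lattice"]
        bg = optics.background_level
        calib = traj.calibration
        grown = traj.lengths > calib.pixel_size
        last = np.array([np.max(np.nonzero(row > bg + 1e-9)[0])
                         for row in lattice[grown]])
        expected = np.ceil(p.seed_length / calib.pixel_size
                           + traj.lengths[grown] / calib.pixel_size) - 1
        assert np.all(np.abs(last - expected) <= 1)

    def test_seed_channel_static_across_frames(self):
        traj = model.simulate_condition(model.BASELINE_PARAMS, 1, 300.0, master_seed=1)[0]
        kymo = model.render_kymograph(traj, model.fit_roi(traj), rng_seed=0)
        seed = kymo.channels["seed"]
        assert np.allclose(seed, seed[0][None, :])

    def test_raster_dimensions(self):
        traj = model.simulate_condition(model.BASELINE_PARAMS, 1, 300.0, master_seed=1)[0]
        optics = model.fit_roi(traj)
        kymo = model.render_kymograph(traj, optics, rng_seed=0)
        assert kymo.channels["lattice"].shape == (traj.frame_times.size, optics.roi_length)

    def test_trajectory_exceeding_roi_errors(self):
        traj = model.simulate_condition(model.BASELINE_PARAMS, 1, 1200.0, master_seed=1)[0]
        with pytest.raises(ModelError):
            model.render_kymograph(traj, OpticsConfig(roi_length=16), rng_seed=0)

    def test_noise_reproducible_under_seed(self):
        traj = model.simulate_condition(model.BASELINE_PARAMS, 1, 300.0, master_seed=1)[0]
        optics = model.fit_roi(traj, OpticsConfig(noise_sigma=10.0))
        a = model.render_kymograph(traj, optics, rng_seed=5)
        b = model.render_kymograph(traj, optics, rng_seed=5)
        assert np.array_equal(a.channels["lattice"], b.channels["lattice"])


class TestExpectedDynamics:
    def test_two_state_rates(self):
        exp = model.expected_dynamics(TWO_STATE)
        assert exp.f_cat == pytest.approx(0.5)
        assert exp.f_res == pytest.approx(2.0)
        assert exp.pause_fraction == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_growth_pause_chain(self):
        p = DynamicsParameters(v_g=1.0, v_s=1.0, k_gp=1.0, k_pg=1.0,
                               k_gs=0.0, k_ps=0.0, k_sg=1.0)
        exp = model.expected_dynamics(p)
        assert exp.pause_fraction == pytest.approx(0.5)
        assert exp.f_cat == pytest.approx(0.0, abs=1e-12)

    def test_full_rate_vector_matches_long_path_event_counting(self):
        p = DynamicsParameters(v_g=1.0, v_s=0.0, k_gs=0.5, k_gp=1.0, k_pg=3.0,
                               k_ps=0.25, k_sg=2.0, k_sp=0.0, k_nuc=1.0)
        exp = model.expected_dynamics(p)
        path = model.sample_state_path(p, 3e4 * 60.0, rng_seed=9)
        times = path.state_times()
        counts = path.transition_counts()
        t_gp_min = (times[GROWTH] + times["P"]) / 60.0
        f_cat_emp = (counts.get((GROWTH, SHRINK), 0) + counts.get(("P", SHRINK), 0)) / t_gp_min
        f_res_emp = (counts.get((SHRINK, GROWTH), 0) + counts.get((SHRINK, "P"), 0)) \
            / (times[SHRINK] / 60.0)
        pause_emp = times["P"] / (times[GROWTH] + times["P"] + times[SHRINK])
        assert f_cat_emp == pytest.approx(exp.f_cat, rel=0.02)
        assert f_res_emp == pytest.approx(exp.f_res, rel=0.02)
        assert pause_emp == pytest.approx(exp.pause_fraction, rel=0.02)

    def test_absorbing_shrink_state_rejected(self):
        # shrinkage reachable from growth but with no exit: no limiting
        # occupancies exist
        p = DynamicsParameters(v_g=1.0, v_s=1.0, k_gs=0.5, k_sg=0.0,
                               k_gp=0.0, k_pg=0.0, k_ps=0.0, k_sp=0.0)
        with pytest.raises(ModelError):
            model.expected_dynamics(p)

    def test_denominator_conventions_differ_as_expected(self):
        p = model.BASELINE_PARAMS
        incl = model.expected_dynamics(p, "excursion_incl_pauses")
        growth_only = model.expected_dynamics(p, "growth_only")
        assert growth_only.f_cat >= incl.f_cat


class TestSimulateCondition:
    def test_deterministic_for_master_seed(self):
        a = model.simulate_condition(model.BASELINE_PARAMS, 5, 600.0, master_seed=3)
        b = model.simulate_condition(model.BASELINE_PARAMS, 5, 600.0, master_seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.lengths, y.lengths)

    def test_zero_rates_give_uninterrupted_growth(self):
        p = DynamicsParameters(v_g=1.0, v_s=1.0)
        for traj in model.simulate_condition(p, 3, 600.0, master_seed=0):
            assert np.all(np.diff(traj.lengths) > 0)

    def test_invalid_count_rejected(self):
        with pytest.raises(ModelError):
            model.simulate_condition(model.BASELINE_PARAMS, 0, 600.0)

    def test_bhc_like_scales_pause_rates(self):
        p = model.BASELINE_PARAMS
        q = model.bhc_like(p)
        assert q.k_gp == pytest.approx(25 * p.k_gp)
        assert q.k_sp == pytest.approx(25 * p.k_sp)
        assert q.k_pg == pytest.approx(p.k_pg / 2)
        assert q.k_ps == pytest.approx(p.k_ps / 2)
        assert dataclasses.replace(q, k_gp=p.k_gp, k_sp=p.k_sp,
                                   k_pg=p.k_pg, k_ps=p.k_ps) == p
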