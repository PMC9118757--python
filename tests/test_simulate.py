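"""Synthetic generator: motion statistics, rendering physics, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from cargotrack import (
    AcquisitionGeometry,
    DetectionParams,
    GeometryError,
    MotionModel,
    OpticsModel,
    generate_dataset,
    locate_spots,
    read_trajectories,
    read_video_stack,
    render_video,
    simulate_colocalization,
    simulate_motion,
)


class TestSimulateMotion:
    def test_same_seed_is_bit_identical(self, small_geometry):
        model = MotionModel(p_moving=0.5)
        a = simulate_motion(model, small_geometry, 10, seed=7)
        b = simulate_motion(model, small_geometry, 10, seed=7)
        np.testing.assert_array_equal(a.positions_um, b.positions_um)
        np.testing.assert_array_equal(a.phase_go, b.phase_go)
        np.testing.assert_array_equal(a.moving, b.moving)

    def test_absorbing_go_state_yields_single_full_go_phase(self, small_geometry):
        model = MotionModel(go_duration_s=float("inf"), p_moving=1.0)
        truth = simulate_motion(model, small_geometry, 4, seed=1)
        assert truth.phase_go.all()

    def test_go_steps_are_speed_over_rate(self, small_geometry):
        # 1 um/s at 20 Hz advances 50 nm per frame along the branch
        model = MotionModel(
            v_go_um_s=1.0,
            go_duration_s=float("inf"),
            jitter_sd_nm=0.0,
            p_moving=1.0,
            bidirectional=False,
        )
        truth = simulate_motion(model, small_geometry, 3, seed=2)
        steps_nm = (
            np.linalg.norm(np.diff(truth.positions_um, axis=1), axis=2) * 1000.0
        )
        # away from branch-end bounces every step is exactly v/rate
        assert np.median(np.abs(steps_nm - 50.0)) < 1e-9

    def test_moving_fraction_is_planted_by_construction(self, small_geometry):
        truth = simulate_motion(MotionModel(p_moving=0.3), small_geometry, 100, seed=3)
        assert truth.moving_fraction == pytest.approx(0.30)
        assert truth.phase_go[~truth.moving].sum() == 0

    def test_phase_durations_follow_exponential_means(self):
        geom = AcquisitionGeometry(
            sensor_width_px=512, sensor_height_px=512, duration_s=120.0
        )
        model = MotionModel(go_duration_s=2.0, stop_duration_s=1.0, p_moving=1.0)
        truth = simulate_motion(model, geom, 40, seed=4)
        stops = truth.phase_durations_s("stop")
        gos = truth.phase_durations_s("go")
        assert stops.mean() == pytest.approx(1.0, rel=0.15)
        assert gos.mean() == pytest.approx(2.0, rel=0.15)
        # discretized exponential: KS against the fitted exponential is loose
        ks = sps.kstest(stops, "expon", args=(0, stops.mean()))
        assert ks.statistic < 0.1

    def test_branch_outside_fov_rejected(self, small_geometry):
        model = MotionModel(branch=np.array([[0.0, 0.0], [50.0, 0.0]]))
        with pytest.raises(GeometryError):
            simulate_motion(model, small_geometry, 1, seed=0)


class TestRenderVideo:
    def test_background_only_when_no_emitters(self, small_geometry):
        truth = simulate_motion(MotionModel(), small_geometry, 0, seed=0)
        optics = OpticsModel(background_counts=30.0, read_noise_sd=0.0)
        stack = render_video(truth, optics, seed=1)
        assert stack.mean() == pytest.approx(30.0, rel=0.01)

    @pytest.mark.parametrize("object_sigma_nm", [0.0, 100.0, 200.0])
    def test_rendered_width_follows_quadrature_law(self, object_sigma_nm):
        # static point source rendered without noise; the fitted SD must be
        # sqrt(sigma_psf**2 + sigma_obj**2) within 2%
        geom = AcquisitionGeometry(
            sensor_width_px=64, sensor_height_px=64, duration_s=0.05
        )
        model = MotionModel(p_moving=0.0, jitter_sd_nm=0.0)
        truth = simulate_motion(model, geom, 1, seed=5)
        optics = OpticsModel(
            photons_per_frame=20000.0,
            background_counts=0.0,
            read_noise_sd=0.0,
            object_sigma_nm=object_sigma_nm,
        )
        frame = render_video(truth, optics, noise=False)[0]
        params = DetectionParams(
            spot_diameter_px=15, min_mass=100.0, refine="gauss", noise_sigma_factor=1.0
        )
        spots = locate_spots(frame, params)
        assert len(spots) == 1
        expected_px = np.hypot(112.0, object_sigma_nm) / geom.pixel_size_nm
        assert spots["sigma_px"].iloc[0] == pytest.approx(expected_px, rel=0.02)

    def test_mean_of_noisy_frames_approaches_expectation(self):
        geom = AcquisitionGeometry(
            sensor_width_px=48, sensor_height_px=48, duration_s=10.0
        )
        truth = simulate_motion(
            MotionModel(p_moving=0.0, jitter_sd_nm=0.0), geom, 1, seed=6
        )
        optics = OpticsModel(photons_per_frame=500.0, background_counts=20.0)
        noiseless = render_video(truth, optics, noise=False)[0]
        noisy = render_video(truth, optics, seed=7)
        np.testing.assert_allclose(noisy.mean(axis=0), noiseless, atol=1.5)


class TestDatasets:
    def test_generate_dataset_files_and_counts(self, tmp_path, small_geometry):
        paths = generate_dataset(
            tmp_path, MotionModel(p_moving=0.3), OpticsModel(), small_geometry,
            n_particles=10, seed=8,
        )
        stack, meta = read_video_stack(paths["video"])
        assert meta["n_frames"] == small_geometry.n_frames
        truth = read_trajectories(paths["truth_trajectories"])
        assert truth["particle_id"].nunique() == 10
        assert len(truth) == 10 * small_geometry.n_frames

    def test_zero_particles_gives_empty_truth(self, tmp_path, small_geometry):
        paths = generate_dataset(
            tmp_path, MotionModel(), OpticsModel(), small_geometry, 0, seed=9
        )
        assert len(read_trajectories(paths["truth_trajectories"])) == 0

    def test_planted_colocalized_fraction_by_construction(self):
        geom = AcquisitionGeometry(
            sensor_width_px=256, sensor_height_px=256, duration_s=10.0
        )
        green, red, fraction = simulate_colocalization(
            MotionModel(), geom, n_green=10, coloc_fraction=0.4, n_distractors=5, seed=10
        )
        assert fraction == pytest.approx(0.40)
        assert green.n_particles == 10
        assert red.n_particles == 4 + 5
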