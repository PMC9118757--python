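"""Confinement-ratio profile, phase parsing and transport parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cargotrack import (
    AcquisitionGeometry,
    Phase,
    PhaseParams,
    classify_moving,
    confinement_ratio_profile,
    parse_phases,
    phase_labels,
    summarize_fov,
    transport_parameters,
    transport_table,
)
from conftest import make_trajectory
from _reference import reference_phase_labels

import pandas as pd


class TestConfinementRatio:
    def test_straight_run_is_fully_directed(self):
        traj = make_trajectory(np.arange(50.0), np.zeros(50))
        ratio = confinement_ratio_profile(traj, PhaseParams(window_frames=5))
        np.testing.assert_allclose(ratio, 1.0)

    def test_out_and_back_is_confined_at_the_turn(self):
        x = np.concatenate([np.arange(10.0), np.arange(8.0, -1.0, -1)])
        traj = make_trajectory(x, np.zeros_like(x))
        ratio = confinement_ratio_profile(traj, PhaseParams(window_frames=5))
        assert ratio[9] == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_window_gives_sqrt2_over_2(self):
        traj = make_trajectory([0.0, 1.0, 1.0], [0.0, 0.0, 1.0])
        ratio = confinement_ratio_profile(traj, PhaseParams(window_frames=3))
        assert ratio[1] == pytest.approx(math.sqrt(2) / 2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 80)).cumsum(axis=1)
        a = confinement_ratio_profile(make_trajectory(x, y))
        b = confinement_ratio_profile(make_trajectory(17.0 * x, 17.0 * y))
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_short_trajectory_uses_whole_track_ratio(self):
        traj = make_trajectory([0.0, 1.0], [0.0, 0.0])
        ratio = confinement_ratio_profile(traj, PhaseParams(window_frames=5))
        np.testing.assert_allclose(ratio, 1.0)


class TestParsePhases:
    def test_pure_run_is_one_go_phase(self, geometry):
        traj = make_trajectory(np.arange(100.0), np.zeros(100))
        phases = parse_phases(traj, geometry)
        assert [p.kind for p in phases] == ["go"]
        assert phases[0].n_frames == 100

    def test_stationary_jitter_is_one_stop_phase(self, geometry):
        rng = np.random.default_rng(1)
        traj = make_trajectory(
            10 + 0.05 * rng.normal(size=100), 10 + 0.05 * rng.normal(size=100)
        )
        phases = parse_phases(traj, geometry)
        assert [p.kind for p in phases] == ["stop"]

    def test_run_pause_run_recovers_three_phases(self, geometry):
        # 2 s run, 1 s pause, 2 s run at 20 Hz; boundaries within half a window
        params = PhaseParams()
        step = 0.625  # 50 nm at 80 nm px
        x = np.concatenate(
            [np.arange(40) * step, np.full(20, 39 * step),
             39 * step + np.arange(1, 41) * step]
        )
        traj = make_trajectory(x, np.zeros_like(x))
        phases = parse_phases(traj, geometry, params)
        assert [p.kind for p in phases] == ["go", "stop", "go"]
        half = params.window_frames // 2
        assert abs(phases[1].start_idx - 40) <= half + 1
        assert abs(phases[1].end_idx - 59) <= half + 1

    def test_partition_property(self, geometry):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 200)).cumsum(axis=1)
        traj = make_trajectory(x, y)
        phases = parse_phases(traj, geometry)
        assert phases[0].start_idx == 0
        assert phases[-1].end_idx == 199
        for prev, nxt in zip(phases, phases[1:]):
            assert nxt.start_idx == prev.end_idx + 1
            assert nxt.kind != prev.kind
        total = sum(p.duration_s for p in phases)
        assert total == pytest.approx(200 / geometry.frame_rate_hz)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(10, 150),
        window=st.sampled_from([3, 5, 9]),
        min_phase=st.integers(1, 6),
        drift=st.floats(0.0, 1.0),
    )
    def test_labels_match_bruteforce_reference(self, seed, n, window, min_phase, drift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n).cumsum() + drift * np.arange(n)
        y = rng.normal(size=n).cumsum()
        traj = make_trajectory(x, y)
        params = PhaseParams(window_frames=window, min_phase_frames=min_phase)
        ours = phase_labels(traj, params)
        ref = reference_phase_labels(
            list(x), list(y), window, params.confinement_threshold, min_phase
        )
        assert list(ours) == ref


class TestTransportParameters:
    def _phases(self):
        return [
            Phase("go", 0, 199, 0, 199, 10.0, 10.0, 10.0),
            Phase("stop", 200, 299, 200, 299, 5.0, 0.1, 0.01),
        ]

    def test_worked_example(self, geometry):
        # 10 um in 10 s, then a 5 s pause (15 s observed)
        traj = make_trajectory(np.zeros(300), np.zeros(300))
        tp = transport_parameters(traj, self._phases(), geometry)
        assert tp.velocity_um_s == pytest.approx(1.0)
        assert tp.run_length_um == pytest.approx(10.0)
        assert tp.pausing_time_s == pytest.approx(5.0)
        assert tp.pausing_frequency_per_min == pytest.approx(4.0)
        assert tp.total_length_um == pytest.approx(10.0)
        assert (tp.n_go, tp.n_stop) == (1, 1)

    def test_all_stop_trajectory_flags_velocity(self, geometry):
        rng = np.random.default_rng(3)
        traj = make_trajectory(
            50 + 0.05 * rng.normal(size=240), 50 + 0.05 * rng.normal(size=240)
        )
        phases = parse_phases(traj, geometry)
        tp = transport_parameters(traj, phases, geometry)
        assert math.isnan(tp.velocity_um_s)
        assert tp.total_length_um == 0.0
        assert tp.pausing_frequency_per_min == pytest.approx(1 / (12.0 / 60.0))

    def test_resampling_preserves_velocity_and_durations(self):
        # the same physical run observed at 20 Hz and 40 Hz
        geom20 = AcquisitionGeometry(frame_rate_hz=20.0)
        geom40 = AcquisitionGeometry(frame_rate_hz=40.0)
        x20 = np.arange(100) * 0.625           # 50 nm steps
        x40 = np.arange(200) * 0.3125          # 25 nm steps, same duration
        tp20 = transport_parameters(
            make_trajectory(x20, np.zeros_like(x20)),
            parse_phases(make_trajectory(x20, np.zeros_like(x20)), geom20),
            geom20,
        )
        tp40 = transport_parameters(
            make_trajectory(x40, np.zeros_like(x40)),
            parse_phases(make_trajectory(x40, np.zeros_like(x40)), geom40),
            geom40,
        )
        assert tp20.velocity_um_s == pytest.approx(tp40.velocity_um_s, rel=0.02)
        assert tp20.duration_s == pytest.approx(tp40.duration_s)


class TestClassifyAndSummarize:
    def test_static_jitter_is_not_moving(self, geometry):
        rng = np.random.default_rng(4)
        traj = make_trajectory(
            20 + 0.05 * rng.normal(size=100), 20 + 0.05 * rng.normal(size=100)
        )
        assert not classify_moving(parse_phases(traj, geometry))

    def test_long_run_is_moving(self, geometry):
        traj = make_trajectory(np.arange(200) * 0.625, np.zeros(200))
        assert classify_moving(parse_phases(traj, geometry))

    def test_summary_counts_and_fraction(self, geometry):
        parts = []
        for pid in range(10):
            if pid < 3:
                x = np.arange(100) * 0.625
            else:
                x = np.full(100, 50.0)
            parts.append(make_trajectory(x, np.zeros(100), particle_id=pid))
        table = transport_table(pd.concat(parts, ignore_index=True), geometry)
        summary = summarize_fov(table)
        assert summary.n_particles == 10
        assert summary.n_moving == 3
        assert summary.moving_fraction == pytest.approx(0.30)

    def test_empty_summary_is_flagged(self):
        summary = summarize_fov(pd.DataFrame(columns=["particle_id", "moving"]))
        assert summary.n_particles == 0
        assert math.isnan(summary.moving_fraction)
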