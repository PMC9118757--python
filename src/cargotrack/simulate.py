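"""Ground-truthed synthetic fluorescence videos of intermittent transport.

Cargo motion is a memoryless two-state switcher: *go* phases of exponentially
distributed duration during which the particle advances along a branch
polyline at constant speed, alternating with exponential *stop* phases during
which it only jitters in place. A configurable fraction of particles never
moves at all (static tracers). By default each particle rides its own
horizontal "branch" lane, lanes being spread across the field of view with a
guaranteed minimum lateral spacing so that spots stay optically separated —
the arrangement mimics cargoes on distinct neurites and keeps the linking
problem free of crossing ambiguities, which the tracker does not attempt to
resolve.

Rendering follows the imaging model used throughout the package: an emitter
of physical Gaussian SD ``object_sigma_nm`` imaged through a Gaussian PSF of
SD ``sigma_psf_nm`` produces a spot of SD ``sqrt(sigma_psf**2 +
object_sigma**2)``, integrated over pixel areas; pixel values are
Poisson(signal + background) plus Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .geometry import AcquisitionGeometry

__all__ = [
    "MotionModel",
    "OpticsModel",
    "GroundTruth",
    "simulate_motion",
    "render_frame",
    "iter_rendered_frames",
    "render_video",
    "generate_dataset",
    "simulate_colocalization",
]


@dataclass
class MotionModel:
    """Kinetic parameters of the go/stop cargo model.

    v_go_um_s : speed along the branch during go phases (um/s).
    go_duration_s, stop_duration_s : mean phase durations of the exponential
        switcher; ``inf`` makes the corresponding state absorbing.
    jitter_sd_nm : isotropic positional noise per frame, applied in both
        phases (cargo wiggle plus localization-scale disorder).
    branch : optional (N, 2) polyline in um that *all* particles follow;
        when None each particle is laid on its own lane.
    p_moving : fraction of particles that ever move; the remainder are
        static for the whole video.
    bidirectional : when True every go phase draws a fresh direction (+/-)
        along the branch, as cargoes switch between opposite motors.
    """

    v_go_um_s: float = 1.0
    go_duration_s: float = 2.0
    stop_duration_s: float = 1.0
    jitter_sd_nm: float = 10.0
    branch: np.ndarray | None = None
    p_moving: float = 0.3
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if self.v_go_um_s < 0:
            raise ValidationError("v_go_um_s must be >= 0")
        if not self.go_duration_s > 0 or not self.stop_duration_s > 0:
            raise ValidationError("phase mean durations must be > 0")
        if not 0 <= self.p_moving <= 1:
            raise ValidationError("p_moving must be in [0, 1]")
        if self.branch is not None:
            self.branch = np.asarray(self.branch, dtype=float)
            if self.branch.ndim != 2 or self.branch.shape[1] != 2 or len(self.branch) < 2:
                raise ValidationError("branch must be an (N>=2, 2) polyline in um")


@dataclass
class OpticsModel:
    """Imaging and noise parameters of the renderer.

    sigma_psf_nm : Gaussian PSF SD (112 nm measured on the instrument).
    photons_per_frame : expected total signal per emitter per frame.
    background_counts : mean background per pixel.
    read_noise_sd : Gaussian read noise SD (counts).
    object_sigma_nm : physical Gaussian SD of the emitter; 0 for point-like
        tracers, > 0 for extended organelles.
    """

    sigma_psf_nm: float = 112.0
    photons_per_frame: float = 2000.0
    background_counts: float = 20.0
    read_noise_sd: float = 2.0
    object_sigma_nm: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_psf_nm > 0:
            raise ValidationError("sigma_psf_nm must be > 0")
        if not self.photons_per_frame > 0:
            raise ValidationError("photons_per_frame must be > 0")
        if self.object_sigma_nm < 0:
            raise ValidationError("object_sigma_nm must be >= 0")

    @property
    def spot_sigma_nm(self) -> float:
        """SD of the rendered spot: PSF and object compose in quadrature."""
        return math.hypot(self.sigma_psf_nm, self.object_sigma_nm)


@dataclass
class GroundTruth:
    """Simulator-side truth for recovery tests.

    positions_um : (n_particles, n_frames, 2) true centres, um, (x, y).
    phase_go : (n_particles, n_frames) boolean go labels.
    moving : (n_particles,) True for particles that ever enter a go phase.
    """

    positions_um: np.ndarray
    phase_go: np.ndarray
    moving: np.ndarray
    model: MotionModel
    geometry: AcquisitionGeometry

    @property
    def n_particles(self) -> int:
        return self.positions_um.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[1]

    @property
    def moving_fraction(self) -> float:
        return float(self.moving.mean()) if self.n_particles else math.nan

    def phase_durations_s(self, kind: str = "stop") -> np.ndarray:
        """Pooled true durations (s) of completed go or stop phases of the
        moving particles, excluding phases truncated by the video ends."""
        want_go = kind == "go"
        dt = self.geometry.dt_s
        out = []
        for p in range(self.n_particles):
            if not self.moving[p]:
                continue
            labels = self.phase_go[p]
            start = 0
            for i in range(1, self.n_frames + 1):
                if i == self.n_frames or labels[i] != labels[start]:
                    if start > 0 and i < self.n_frames and labels[start] == want_go:
                        out.append((i - start) * dt)
                    start = i
        return np.asarray(out)

    def pausing_frequency_per_min(self) -> float:
        """Mean true stop-event rate of moving particles, events/min of
        observation (same denominator convention as the analysis)."""
        rates = []
        minutes = self.n_frames * self.geometry.dt_s / 60.0
        for p in range(self.n_particles):
            if not self.moving[p]:
                continue
            labels = self.phase_go[p]
            n_stop = 0
            start = 0
            for i in range(1, self.n_frames + 1):
                if i == self.n_frames or labels[i] != labels[start]:
                    if not labels[start]:
                        n_stop += 1
                    start = i
            rates.append(n_stop / minutes)
        return float(np.mean(rates)) if rates else math.nan

    def to_trajectories(
        self, channel: str = "red", condition: str = "", fov_id: str = "fov0"
    ) -> pd.DataFrame:
        """Truth positions as a trajectory table in pixel coordinates."""
        geom = self.geometry
        n_p, n_f = self.n_particles, self.n_frames
        frames = np.tile(np.arange(n_f), n_p)
        pid = np.repeat(np.arange(n_p), n_f)
        xy_px = self.positions_um.reshape(-1, 2) / geom.um_per_px
        return pd.DataFrame(
            {
                "fov_id": fov_id,
                "condition": condition,
                "channel": channel,
                "particle_id": pid,
                "frame": frames,
                "x_px": xy_px[:, 0],
                "y_px": xy_px[:, 1],
                "sigma_px": 112.0 / geom.pixel_size_nm,
                "intensity": 1.0,
                "background": 0.0,
            }
        )


def _polyline_arcs(branch: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(branch, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_on_polyline(branch: np.ndarray, arcs: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Positions at arc lengths ``s`` (already clipped to [0, length])."""
    x = np.interp(s, arcs, branch[:, 0])
    y = np.interp(s, arcs, branch[:, 1])
    return np.stack([x, y], axis=-1)


def _reflect(s: np.ndarray | float, length: float):
    """Reflect arc positions into [0, length] (bounce at branch ends)."""
    period = 2.0 * length
    s = np.mod(s, period)
    return np.where(s > length, period - s, s)


def _simulate_states(
    n_frames: int,
    dt: float,
    go_mean: float,
    stop_mean: float,
    start_go: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean go labels of one particle from the exponential switcher."""
    labels = np.empty(n_frames, dtype=bool)
    t = 0
    state = start_go
    while t < n_frames:
        mean = go_mean if state else stop_mean
        if math.isinf(mean):
            labels[t:] = state
            break
        dur = max(1, int(round(rng.exponential(mean) / dt)))
        labels[t : t + dur] = state
        t += dur
        state = not state
    return labels


def simulate_motion(
    model: MotionModel,
    geometry: AcquisitionGeometry,
    n_particles: int,
    seed: int = 0,
) -> GroundTruth:
    """Simulate true positions and go/stop labels for ``n_particles``.

    ``round(p_moving * n_particles)`` particles move; the rest are static
    for the whole video. With the default lane layout particles are spread
    over horizontal branches with at least ~10 px of lateral spacing; a
    user-supplied ``model.branch`` is shared by all particles and must lie
    inside the field of view. The same seed yields bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n_frames = geometry.n_frames
    dt = geometry.dt_s
    width_um = geometry.width_um
    height_um = geometry.height_um
    margin_um = 10 * geometry.um_per_px

    if model.branch is not None:
        br = model.branch
        if (
            br[:, 0].min() < 0
            or br[:, 1].min() < 0
            or br[:, 0].max() > width_um
            or br[:, 1].max() > height_um
        ):
            raise GeometryError("branch polyline extends outside the field of view")
        branches = [br] * n_particles
    else:
        usable = height_um - 2 * margin_um
        if n_particles > 1:
            ys = margin_um + usable * (np.arange(n_particles) + 0.5) / n_particles
        else:
            ys = np.array([height_um / 2.0])
        ys = rng.permutation(ys)
        branches = [
            np.array([[margin_um, y], [width_um - margin_um, y]]) for y in ys
        ]

    n_moving = int(round(model.p_moving * n_particles))
    moving = np.zeros(n_particles, dtype=bool)
    moving[rng.permutation(n_particles)[:n_moving]] = True

    positions = np.empty((n_particles, n_frames, 2))
    phase_go = np.zeros((n_particles, n_frames), dtype=bool)
    jitter_um = model.jitter_sd_nm / 1000.0

    for p in range(n_particles):
        branch = branches[p]
        arcs = _polyline_arcs(branch)
        length = arcs[-1]
        s0 = rng.uniform(0.25, 0.75) * length
        if moving[p]:
            if math.isinf(model.go_duration_s):
                start_go = True
            elif math.isinf(model.stop_duration_s):
                start_go = False
            else:
                p_go = model.go_duration_s / (model.go_duration_s + model.stop_duration_s)
                start_go = bool(rng.uniform() < p_go)
            labels = _simulate_states(
                n_frames, dt, model.go_duration_s, model.stop_duration_s, start_go, rng
            )
            phase_go[p] = labels
            s = np.full(n_frames, s0)
            pos = s0
            direction = 1.0 if (not model.bidirectional or rng.uniform() < 0.5) else -1.0
            prev_go = labels[0]
            for f in range(n_frames):
                if labels[f]:
                    if model.bidirectional and not prev_go:
                        direction = 1.0 if rng.uniform() < 0.5 else -1.0
                    pos += direction * model.v_go_um_s * dt
                prev_go = labels[f]
                s[f] = pos
            s = _reflect(s, length)
            positions[p] = _point_on_polyline(branch, arcs, s)
        else:
            positions[p] = _point_on_polyline(branch, arcs, np.full(n_frames, s0))
        positions[p] += rng.normal(0.0, jitter_um, size=(n_frames, 2))

    return GroundTruth(
        positions_um=positions,
        phase_go=phase_go,
        moving=moving,
        model=model,
        geometry=geometry,
    )


def _stamp(
    frame: np.ndarray, x_px: float, y_px: float, sigma_px: float, photons: float
) -> None:
    """Add one pixel-integrated Gaussian emitter to ``frame`` in place."""
    from scipy.special import erf

    h, w = frame.shape
    r = max(3, int(math.ceil(4.0 * sigma_px)))
    x0, x1 = int(math.floor(x_px)) - r, int(math.floor(x_px)) + r + 1
    y0, y1 = int(math.floor(y_px)) - r, int(math.floor(y_px)) + r + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    s = sigma_px * math.sqrt(2.0)
    ex = np.arange(x0, x1)
    ey = np.arange(y0, y1)
    gx = 0.5 * (erf((ex + 0.5 - x_px) / s) - erf((ex - 0.5 - x_px) / s))
    gy = 0.5 * (erf((ey + 0.5 - y_px) / s) - erf((ey - 0.5 - y_px) / s))
    frame[y0:y1, x0:x1] += photons * np.outer(gy, gx)


def render_frame(
    truth: GroundTruth,
    frame_index: int,
    optics: OpticsModel,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render one frame; without ``noise`` returns the expectation image."""
    geom = truth.geometry
    h, w = geom.frame_height_px, geom.sensor_width_px
    expect = np.full((h, w), float(optics.background_counts))
    sigma_px = optics.spot_sigma_nm / geom.pixel_size_nm
    for p in range(truth.n_particles):
        x_um, y_um = truth.positions_um[p, frame_index]
        _stamp(
            expect,
            x_um / geom.um_per_px,
            y_um / geom.um_per_px,
            sigma_px,
            optics.photons_per_frame,
        )
    if not noise:
        return expect.astype(np.float32)
    rng = rng if rng is not None else np.random.default_rng()
    out = rng.poisson(expect).astype(np.float32)
    if optics.read_noise_sd > 0:
        out += rng.normal(0.0, optics.read_noise_sd, size=expect.shape).astype(np.float32)
    return out


def iter_rendered_frames(
    truth: GroundTruth,
    optics: OpticsModel,
    seed: int = 0,
    noise: bool = True,
) -> Iterator[np.ndarray]:
    """Stream rendered frames one at a time (memory-bounded for long videos)."""
    rng = np.random.default_rng(seed)
    for f in range(truth.n_frames):
        yield render_frame(truth, f, optics, rng, noise)


def render_video(
    truth: GroundTruth,
    optics: OpticsModel,
    seed: int = 0,
    noise: bool = True,
) -> np.ndarray:
    """Render the full stack as a (n_frames, height, width) float32 array."""
    return np.stack(list(iter_rendered_frames(truth, optics, seed, noise)))


def generate_dataset(
    out_dir: str | Path,
    model: MotionModel,
    optics: OpticsModel,
    geometry: AcquisitionGeometry,
    n_particles: int,
    seed: int = 0,
    condition: str = "",
    fov_id: str = "fov0",
) -> dict[str, Path]:
    """Write a complete synthetic dataset: video, truth table, truth summary.

    Returns the paths of ``video.tif``, ``truth_trajectories.csv`` and
    ``truth_summary.csv``.
    """
    from .io import write_trajectories, write_video_stack

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_motion(model, geometry, n_particles, seed)
    video_path = out_dir / "video.tif"
    write_video_stack(video_path, render_video(truth, optics, seed=seed + 1))
    traj_path = out_dir / "truth_trajectories.csv"
    write_trajectories(truth.to_trajectories(condition=condition, fov_id=fov_id), traj_path)
    summary = pd.DataFrame(
        {
            "fov_id": [fov_id],
            "condition": [condition],
            "n_particles": [n_particles],
            "n_moving": [int(truth.moving.sum())],
            "moving_fraction": [truth.moving_fraction],
            "v_go_um_s": [model.v_go_um_s],
            "go_duration_s": [model.go_duration_s],
            "stop_duration_s": [model.stop_duration_s],
        }
    )
    summary_path = out_dir / "truth_summary.csv"
    summary.to_csv(summary_path, index=False)
    return {
        "video": video_path,
        "truth_trajectories": traj_path,
        "truth_summary": summary_path,
    }


def simulate_colocalization(
    model: MotionModel,
    geometry: AcquisitionGeometry,
    n_green: int,
    coloc_fraction: float,
    n_distractors: int,
    pair_jitter_nm: float = 50.0,
    seed: int = 0,
) -> tuple[GroundTruth, GroundTruth, float]:
    """Two-channel truth with a planted colocalized fraction.

    All green particles move. A ``round(coloc_fraction * n_green)`` subset is
    duplicated into the red channel with independent per-frame jitter of SD
    ``pair_jitter_nm`` (a bound pair rides the same cargo); the red channel
    additionally carries ``n_distractors`` independent trajectories. Returns
    (green truth, red truth, true colocalized fraction).
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValidationError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    green_model = MotionModel(
        v_go_um_s=model.v_go_um_s,
        go_duration_s=model.go_duration_s,
        stop_duration_s=model.stop_duration_s,
        jitter_sd_nm=model.jitter_sd_nm,
        branch=model.branch,
        p_moving=1.0,
        bidirectional=model.bidirectional,
    )
    green = simulate_motion(green_model, geometry, n_green, seed=int(rng.integers(2**31)))
    n_pairs = int(round(coloc_fraction * n_green))
    paired = rng.permutation(n_green)[:n_pairs]

    distractors = simulate_motion(
        MotionModel(
            v_go_um_s=model.v_go_um_s,
            go_duration_s=model.go_duration_s,
            stop_duration_s=model.stop_duration_s,
            jitter_sd_nm=model.jitter_sd_nm,
            p_moving=model.p_moving,
            bidirectional=model.bidirectional,
        ),
        geometry,
        n_distractors,
        seed=int(rng.integers(2**31)),
    )

    red_positions = np.concatenate(
        [
            green.positions_um[paired]
            + rng.normal(0.0, pair_jitter_nm / 1000.0, size=(n_pairs, green.n_frames, 2)),
            distractors.positions_um,
        ]
    )
    red_phase = np.concatenate([green.phase_go[paired], distractors.phase_go])
    red_moving = np.concatenate([green.moving[paired], distractors.moving])
    red = GroundTruth(
        positions_um=red_positions,
        phase_go=red_phase,
        moving=red_moving,
        model=model,
        geometry=geometry,
    )
    true_fraction = n_pairs / n_green if n_green else math.nan
    return green, red, true_fraction
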