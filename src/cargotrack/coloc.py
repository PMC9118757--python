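"""Dynamic two-channel trajectory colocalization and branch ROI intensity.

Colocalization is decided at the trajectory level, not frame-wise: a green
(assembly) trajectory and a red (cargo/lysosome) trajectory colocalize when
they share enough common frames and the summary (median by default) of their
inter-channel distances over those frames stays below a spatial tolerance —
two labels riding one cargo stay close for the whole overlap, whereas chance
encounters do not. The reported fraction counts, among *moving* green
trajectories, those with at least one qualifying red partner.

Branch ROI intensity implements the standard mean-minus-background readout:
mean counts per pixel inside a polygonal region enclosing a neurite segment,
minus the mean over a background polygon drawn where no branches run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .errors import ValidationError
from .geometry import AcquisitionGeometry
from .motion import PhaseParams, classify_moving, parse_phases

__all__ = [
    "ColocalizationParams",
    "ColocalizationResult",
    "BranchRoi",
    "match_trajectories",
    "branch_roi_intensity",
]


@dataclass
class ColocalizationParams:
    """Criteria for pairing trajectories across channels.

    max_distance_nm : largest summary distance that still counts as bound
        (default 320 nm = 4 px at 80 nm, about one diffraction radius).
    min_overlap_frames : minimum number of common frames (1 s at 20 Hz).
    summary_statistic : 'median' (robust, default) or 'mean' distance over
        the temporal overlap.
    """

    max_distance_nm: float = 320.0
    min_overlap_frames: int = 20
    summary_statistic: str = "median"

    def __post_init__(self) -> None:
        if not self.max_distance_nm > 0:
            raise ValidationError("max_distance_nm must be > 0")
        if self.min_overlap_frames < 1:
            raise ValidationError("min_overlap_frames must be >= 1")
        if self.summary_statistic not in ("median", "mean"):
            raise ValidationError("summary_statistic must be 'median' or 'mean'")


@dataclass
class ColocalizationResult:
    """Pair table plus the colocalized fraction of moving green trajectories.

    ``pairs`` has one row per green trajectory with a qualifying partner:
    columns ``green_id, red_id, n_overlap, distance_nm, green_moving``.
    ``colocalized_fraction`` is NaN when no green trajectory moves.
    """

    pairs: pd.DataFrame
    colocalized_fraction: float
    n_green_moving: int
    n_green_total: int


@dataclass
class BranchRoi:
    """Polygonal region over a neurite branch plus a background region.

    Vertices are (x, y) pixel coordinates; ``length_um`` records the branch
    length covered (30 um is the standard segment).
    """

    polygon: np.ndarray
    background_polygon: np.ndarray
    length_um: float = 30.0

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.background_polygon = np.asarray(self.background_polygon, dtype=float)
        for name in ("polygon", "background_polygon"):
            poly = getattr(self, name)
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise ValidationError(f"{name} must be an (N>=3, 2) vertex list")


def _summary_distance(
    a: pd.DataFrame, b: pd.DataFrame, params: ColocalizationParams, nm_per_px: float
) -> tuple[int, float]:
    """Common-frame count and summary inter-trajectory distance in nm."""
    merged = a.merge(b, on="frame", suffixes=("_a", "_b"))
    n = len(merged)
    if n == 0:
        return 0, math.inf
    d_px = np.hypot(
        merged["x_px_a"] - merged["x_px_b"], merged["y_px_a"] - merged["y_px_b"]
    )
    stat = np.median if params.summary_statistic == "median" else np.mean
    return n, float(stat(d_px) * nm_per_px)


def match_trajectories(
    green: pd.DataFrame,
    red: pd.DataFrame,
    geometry: AcquisitionGeometry,
    params: ColocalizationParams | None = None,
    phase_params: PhaseParams | None = None,
) -> ColocalizationResult:
    """Pair green trajectories with red partners and count the moving
    colocalized fraction.

    Both tables must already share one coordinate frame (see
    :func:`cargotrack.io.split_channels`). Every green trajectory is
    assigned at most its nearest qualifying red partner; the fraction is
    computed over moving green trajectories only.
    """
    params = params or ColocalizationParams()
    phase_params = phase_params or PhaseParams()
    nm_per_px = geometry.pixel_size_nm

    red_groups = {
        rid: grp[["frame", "x_px", "y_px"]].sort_values("frame")
        for rid, grp in red.groupby("particle_id", sort=True)
    }

    rows = []
    n_moving = 0
    n_total = 0
    for gid, ggrp in green.groupby("particle_id", sort=True):
        ggrp = ggrp.sort_values("frame")
        n_total += 1
        if len(ggrp) >= 2:
            phases = parse_phases(ggrp, geometry, phase_params)
            moving = classify_moving(phases, phase_params)
        else:
            moving = False
        n_moving += moving
        best = None
        gsub = ggrp[["frame", "x_px", "y_px"]]
        for rid, rgrp in red_groups.items():
            n_overlap, dist = _summary_distance(gsub, rgrp, params, nm_per_px)
            if n_overlap < params.min_overlap_frames or dist > params.max_distance_nm:
                continue
            if best is None or dist < best[2]:
                best = (rid, n_overlap, dist)
        if best is not None:
            rows.append(
                {
                    "green_id": gid,
                    "red_id": best[0],
                    "n_overlap": best[1],
                    "distance_nm": best[2],
                    "green_moving": bool(moving),
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["green_id", "red_id", "n_overlap", "distance_nm", "green_moving"]
    )
    if n_moving:
        fraction = float(pairs["green_moving"].sum()) / n_moving if len(pairs) else 0.0
    else:
        fraction = math.nan
    return ColocalizationResult(
        pairs=pairs,
        colocalized_fraction=fraction,
        n_green_moving=n_moving,
        n_green_total=n_total,
    )


def branch_roi_intensity(image: np.ndarray, roi: BranchRoi) -> float:
    """Background-subtracted mean counts per pixel over a branch ROI.

    Pixels whose centres fall inside the polygon are averaged; the mean over
    the background polygon is subtracted. Overlapping ROI and background
    polygons bias the result low and trigger a warning.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xx.ravel(), yy.ravel()])

    def mean_inside(poly: np.ndarray, name: str) -> tuple[float, np.ndarray]:
        mask = MplPath(poly).contains_points(centers).reshape(h, w)
        if not mask.any():
            raise ValidationError(f"{name} contains no pixel centres")
        return float(image[mask].mean()), mask

    roi_mean, roi_mask = mean_inside(roi.polygon, "polygon")
    bg_mean, bg_mask = mean_inside(roi.background_polygon, "background_polygon")
    if (roi_mask & bg_mask).any():
        warnings.warn(
            "ROI and background polygons overlap; intensity will be underestimated",
            stacklevel=2,
        )
    return roi_mean - bg_mean
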