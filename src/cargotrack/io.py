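"""Video and trajectory-table I/O, and dual-view channel splitting.

Videos are multi-page TIFF stacks. Trajectory tables are plain
comma-delimited text with one row per localized spot and a fixed header; a
leading comment line declares the numeric precision of the float columns so
round-trips are reproducible within a stated tolerance. No binary containers
are used anywhere.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import FormatError, GeometryError, ValidationError
from .geometry import AcquisitionGeometry

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_video_stack",
    "write_video_stack",
    "split_channels",
    "write_trajectories",
    "read_trajectories",
]

TRAJECTORY_COLUMNS = [
    "fov_id",
    "condition",
    "channel",
    "particle_id",
    "frame",
    "x_px",
    "y_px",
    "sigma_px",
    "intensity",
    "background",
]

#: Significant digits written for float columns, declared in the file header.
_FLOAT_DIGITS = 9
_HEADER_COMMENT = f"# cargotrack trajectories v1; float precision %.{_FLOAT_DIGITS}g"


def read_video_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF as a (n_frames, height, width) array.

    Single-page files come back with a leading axis of length 1. Metadata
    currently carries the source path and frame count.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise FormatError(f"{path}: TIFF contains no pages")
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise FormatError(f"{path}: inconsistent page shapes {sorted(shapes)}")
        stack = tif.asarray()
    if stack.ndim == 2:
        stack = stack[None, ...]
    return stack, {"path": str(path), "n_frames": stack.shape[0]}


def write_video_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (n_frames, height, width) array as a multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValidationError("video stack must be 3-D (frame, row, column)")
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def split_channels(
    frame: np.ndarray, geometry: AcquisitionGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Split one dual-view frame into registered (green, red) views.

    The green channel occupies the top ``view_height_px`` rows, the red
    channel the rows directly below. The red view is translated by
    ``geometry.channel_offset_px`` (dx, dy) so both views share the green
    view's coordinate frame.
    """
    if not geometry.dual_view:
        raise GeometryError("split_channels requires dual_view geometry")
    frame = np.asarray(frame)
    vh = geometry.view_height_px
    if frame.ndim != 2 or frame.shape[0] < 2 * vh:
        raise GeometryError(
            f"frame of shape {frame.shape} too small for two {vh}-row views"
        )
    green = frame[:vh, :]
    red = frame[vh : 2 * vh, :]
    dx, dy = geometry.channel_offset_px
    if dx != 0 or dy != 0:
        # ndimage.shift takes (row, col) = (dy, dx); linear interpolation is
        # exact for integer offsets
        red = ndimage.shift(red.astype(float), (dy, dx), order=1, mode="constant", cval=0.0)
    return green, red


def write_trajectories(trajectories: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory table as delimited text with a precision header."""
    path = Path(path)
    df = pd.DataFrame(trajectories)
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory table missing required columns: {missing}")
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT + "\n")
        df.to_csv(fh, index=False, float_format=f"%.{_FLOAT_DIGITS}g")


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a trajectory table, tolerating unknown columns with a warning."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in TRAJECTORY_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    return df
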