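"""Acquisition geometry: pixel size, frame rate and sensor layout.

All spatial quantities are stored once, in pixel units, and converted to
physical units through ``pixel_size_nm`` at analysis time. Coordinates are
0-based with pixel centres at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["AcquisitionGeometry"]


@dataclass
class AcquisitionGeometry:
    """Geometry and timing of one video acquisition.

    Defaults describe a 2-minute, 20 frame/s recording on a 1004x1002 pixel
    EMCCD with 80 nm pixels in the sample plane. In dual-view mode one sensor
    carries the same rectangular field of view twice, side by side in two
    spectral channels of ``view_height_px`` rows each; ``channel_offset_px``
    is the rigid (dx, dy) translation that registers the red view onto the
    green one.
    """

    pixel_size_nm: float = 80.0
    frame_rate_hz: float = 20.0
    duration_s: float = 120.0
    sensor_width_px: int = 1004
    sensor_height_px: int = 1002
    dual_view: bool = False
    view_height_px: int = 501
    channel_offset_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValidationError("pixel_size_nm must be > 0")
        if not self.frame_rate_hz > 0:
            raise ValidationError("frame_rate_hz must be > 0")
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be > 0")
        if self.dual_view and 2 * self.view_height_px > self.sensor_height_px:
            raise ValidationError(
                "dual view requires 2 * view_height_px <= sensor_height_px"
            )
        self.channel_offset_px = tuple(self.channel_offset_px)  # type: ignore[assignment]

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def um_per_px(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def frame_height_px(self) -> int:
        """Rows of one analyzed view (half sensor in dual-view mode)."""
        return self.view_height_px if self.dual_view else self.sensor_height_px

    @property
    def width_um(self) -> float:
        return self.sensor_width_px * self.um_per_px

    @property
    def height_um(self) -> float:
        return self.frame_height_px * self.um_per_px
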