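import numpy as np
import pandas as pd
import pytest

from cargotrack import AcquisitionGeometry


@pytest.fixture
def small_geometry() -> AcquisitionGeometry:
    """A 128x128 px, 5 s field of view for fast rendering tests."""
    return AcquisitionGeometry(
        sensor_width_px=128, sensor_height_px=128, duration_s=5.0
    )


@pytest.fixture
def geometry() -> AcquisitionGeometry:
    """Default full-sensor acquisition geometry."""
    return AcquisitionGeometry()


def make_trajectory(x_px, y_px, frames=None, particle_id=0, **extra) -> pd.DataFrame:
    """Build a minimal trajectory table from coordinate arrays."""
    x = np.asarray(x_px, dtype=float)
    y = np.asarray(y_px, dtype=float)
    if frames is None:
        frames = np.arange(len(x))
    df = pd.DataFrame(
        {
            "fov_id": "fov0",
            "condition": "",
            "channel": "red",
            "particle_id": particle_id,
            "frame": np.asarray(frames, dtype=int),
            "x_px": x,
            "y_px": y,
            "sigma_px": 1.4,
            "intensity": 1000.0,
            "background": 10.0,
        }
    )
    for key, val in extra.items():
        df[key] = val
    return df
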