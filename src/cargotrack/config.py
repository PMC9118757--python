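"""Configuration: defaults, YAML file values, then explicit overrides.

One YAML document governs the whole pipeline. Keys may be grouped under the
section names ``geometry``, ``detection``, ``phases``, ``colocalization`` and
``psf``, or given flat at the top level (every parameter name is unique
across sections, so flat keys are unambiguous). Precedence is
defaults < file < overrides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .coloc import ColocalizationParams
from .detect import DetectionParams
from .errors import ConfigError, ValidationError
from .geometry import AcquisitionGeometry
from .morphometry import PsfConstants, compute_psf_constants
from .motion import PhaseParams

__all__ = ["AnalysisConfig", "load_config"]

_SECTIONS = {
    "geometry": AcquisitionGeometry,
    "detection": DetectionParams,
    "phases": PhaseParams,
    "colocalization": ColocalizationParams,
    "psf": PsfConstants,
}


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, grouped per stage."""

    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    detection: DetectionParams = field(default_factory=DetectionParams)
    phases: PhaseParams = field(default_factory=PhaseParams)
    colocalization: ColocalizationParams = field(default_factory=ColocalizationParams)
    psf: PsfConstants = field(default_factory=compute_psf_constants)


def _field_index() -> dict[str, tuple[str, str, type]]:
    """Flat parameter name -> (section, field name, annotated type)."""
    index: dict[str, tuple[str, str, type]] = {}
    for section, cls in _SECTIONS.items():
        for f in dataclasses.fields(cls):
            index[f.name] = (section, f.name, f.type)  # names unique by design
    return index


_NUMERIC_FIELDS = {
    "pixel_size_nm", "frame_rate_hz", "duration_s", "sensor_width_px",
    "sensor_height_px", "view_height_px", "spot_diameter_px", "min_mass",
    "max_displacement_px", "memory_frames", "min_track_frames",
    "noise_sigma_factor", "confinement_threshold", "window_frames",
    "min_phase_frames", "min_directed_displacement_um", "max_distance_nm",
    "min_overlap_frames", "sigma_psf_nm", "airy_radius_nm",
    "sigma_psf_empirical_nm",
}
_INT_FIELDS = {
    "sensor_width_px", "sensor_height_px", "view_height_px",
    "spot_diameter_px", "memory_frames", "min_track_frames",
    "window_frames", "min_phase_frames", "min_overlap_frames",
}


def _coerce(key: str, value: Any) -> Any:
    if key in _NUMERIC_FIELDS:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValidationError(f"config key {key!r} requires a numeric value, got {value!r}")
        return int(value) if key in _INT_FIELDS else float(value)
    return value


def _flatten(doc: Mapping[str, Any]) -> dict[str, Any]:
    """Merge sectioned and flat keys into one flat mapping."""
    flat: dict[str, Any] = {}
    for key, value in doc.items():
        if key in _SECTIONS and isinstance(value, Mapping):
            for sub, subval in value.items():
                flat[sub] = subval
        else:
            flat[key] = value
    return flat


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from defaults, a file and overrides.

    ``path`` may be None (defaults only). Unknown keys raise; non-numeric
    values for numeric keys raise a validation error naming the key.
    """
    values: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        try:
            doc = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not parseable as YAML: {exc}") from exc
        if doc is None:
            doc = {}
        if not isinstance(doc, Mapping):
            raise ConfigError(f"{path}: top level must be a key-value mapping")
        values.update(_flatten(doc))
    if overrides:
        values.update(_flatten(dict(overrides)))

    index = _field_index()
    per_section: dict[str, dict[str, Any]] = {name: {} for name in _SECTIONS}
    for key, value in values.items():
        if key == "channel_offset_px":
            per_section["geometry"][key] = tuple(float(v) for v in value)
            continue
        if key not in index:
            raise ConfigError(f"unknown configuration key: {key!r}")
        section, fname, _ = index[key]
        per_section[section][fname] = _coerce(key, value)

    return AnalysisConfig(
        **{name: cls(**per_section[name]) for name, cls in _SECTIONS.items()}
    )
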