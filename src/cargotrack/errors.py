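"""Exception hierarchy shared across the package."""


class CargotrackError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CargotrackError):
    """Configuration file missing or unparseable."""


class ValidationError(CargotrackError, ValueError):
    """A parameter or input value violates its contract."""


class FormatError(CargotrackError):
    """A file does not conform to the expected on-disk format."""


class GeometryError(CargotrackError):
    """An operation is inconsistent with the acquisition geometry."""
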