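"""Exception hierarchy shared across the package."""


class FetalRadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FetalRadError):
    """Invalid configuration value (bad probability, size, grid...)."""


class DegenerateROIError(FetalRadError):
    """Region of interest too small or too thin for the requested feature."""


class GeometryError(FetalRadError):
    """A window or mask does not fit inside the image bounds."""


class ContractViolation(FetalRadError):
    """Caller broke an operation's precondition (e.g. single-class labels)."""


class ImageIOError(FetalRadError):
    """Unreadable or malformed image file; message names the path."""
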