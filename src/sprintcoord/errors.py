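"""Exception hierarchy used across the package."""


class SprintCoordError(Exception):
    """Base class for all package errors."""


class FormatError(SprintCoordError):
    """A file did not match the expected tabular layout."""


class ValidationError(SprintCoordError):
    """Input data violated a structural invariant."""


class SegmentationError(SprintCoordError):
    """Gait events could not be segmented into steps."""


class ParameterError(SprintCoordError):
    """A numeric parameter was outside its valid range."""


class SpanError(SprintCoordError):
    """A time window or event fell outside the recorded span."""


class ConfigError(SprintCoordError):
    """A configuration object was internally inconsistent."""
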