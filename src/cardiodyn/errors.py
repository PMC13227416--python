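"""Exception hierarchy for cardiodyn.

All readers raise :class:`InputFormatError` for malformed files and
:class:`ValidationError` for structurally invalid data; analysis routines
raise :class:`InsufficientDataError` when a series is too short to measure.
"""


class CardiodynError(Exception):
    """Base class for all cardiodyn errors."""


class InputFormatError(CardiodynError):
    """A file does not conform to its documented schema."""


class ValidationError(CardiodynError):
    """Structurally invalid data (bad polygon, non-monotone frames, ...)."""


class InsufficientDataError(CardiodynError):
    """Too few samples/frames for the requested measurement."""


class ConfigError(CardiodynError):
    """Invalid run configuration."""
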