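"""Exception hierarchy shared across the package."""


class MusfaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MusfaError, ValueError):
    """Invalid parameter, geometry, or table content."""


class InputFormatError(MusfaError, ValueError):
    """A file parsed, but its content violates the expected layout."""


class ROITooSmallError(ValidationError):
    """ROI does not admit a single analysis kernel."""
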