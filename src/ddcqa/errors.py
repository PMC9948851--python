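"""Exception hierarchy for the ddcqa package."""


class DDCQAError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(DDCQAError):
    """Rod placement could not satisfy the layout constraints."""


class GeometryError(DDCQAError):
    """Layout and acquisition geometry are inconsistent (e.g. rods outside the field)."""


class RegistrationError(DDCQAError):
    """Template registration failed (correlation below the configured floor)."""


class InsufficientDataError(DDCQAError):
    """Not enough data points to determine the requested fit."""


class DegenerateResampleError(DDCQAError):
    """Too many bootstrap draws could not support a fit."""


class FormatError(DDCQAError):
    """An input file or directory does not conform to the expected format."""
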