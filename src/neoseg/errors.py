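"""Exception hierarchy shared across the package."""


class NeosegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeosegError):
    """A file could not be parsed as a supported volume format."""


class ShapeError(NeosegError):
    """Array geometries (extents, spacing, channels) are incompatible."""


class DegenerateInputError(NeosegError):
    """Input is structurally valid but degenerate (empty foreground,
    non-increasing reference scale, empty tissue class, ...)."""


class UsageError(NeosegError):
    """An operation was called with inconsistent arguments."""
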