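"""Exception types shared across the package."""


class AmsmwError(Exception):
    """Base class for all package errors."""


class DomainError(AmsmwError, ValueError):
    """Invalid input for an operation (bad RROI, empty mask, open contour...)."""


class ImageIOError(AmsmwError, OSError):
    """Unreadable or unwritable image file."""
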