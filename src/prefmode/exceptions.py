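"""Exception hierarchy.

``InvalidInputError`` covers malformed arguments and containers;
``DegenerateDataError`` covers inputs that are structurally valid but carry
no usable signal (all-zero tensors, zero-variance slices) where normalized
quantities would be undefined. ``FormatError`` is raised by the I/O layer
when an on-disk file does not match the documented layout.
"""


class PrefmodeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PrefmodeError, ValueError):
    """Malformed argument or container (bad shape, out-of-range parameter)."""


class DegenerateDataError(PrefmodeError, ValueError):
    """Structurally valid data with no usable signal (e.g. all zeros)."""


class FormatError(PrefmodeError, ValueError):
    """On-disk file does not match the documented serialization layout."""
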