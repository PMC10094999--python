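"""Exception hierarchy.

All calmdx errors derive from :class:`CalmdxError`; most are also ValueError
subclasses so generic callers can catch them without importing calmdx.
"""


class CalmdxError(Exception):
    """Base class for all calmdx errors."""


class FormatError(CalmdxError, ValueError):
    """A file or table does not conform to the expected on-disk format."""


class ValidationError(CalmdxError, ValueError):
    """Input data violates a domain invariant (overlapping windows, gaps...)."""


class RangeError(CalmdxError, ValueError):
    """A value or span is outside the admissible range."""


class DimensionError(CalmdxError, ValueError):
    """Array shapes are inconsistent."""


class NormalizationError(CalmdxError, ValueError):
    """Baseline F0 is zero somewhere, so %dF/F0 is undefined."""


class AssayError(CalmdxError, ValueError):
    """Calibration curve is unusable (non-positive slope, degenerate design)."""
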