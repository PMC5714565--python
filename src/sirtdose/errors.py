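"""Exception hierarchy shared across the package.

All errors derive from :class:`SirtDoseError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin so existing ``ValueError``-style handling keeps
working.
"""


class SirtDoseError(Exception):
    """Base class for all sirtdose errors."""


class FormatError(SirtDoseError, ValueError):
    """A file could not be parsed as the expected format."""


class GeometryError(SirtDoseError, ValueError):
    """Grid/kernel geometries are inconsistent or do not overlap."""


class QuantityError(SirtDoseError, ValueError):
    """An image carries the wrong physical quantity for an operation."""


class MaskError(SirtDoseError, ValueError):
    """A structure mask is empty or incompatible with its grid."""


class KernelError(SirtDoseError, ValueError):
    """A voxel S-value kernel violates its invariants."""


class TimeError(SirtDoseError, ValueError):
    """Reference/administration times are inconsistent."""
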