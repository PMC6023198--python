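"""Exception hierarchy used across the package.

All errors derive from :class:`FetclustError` so callers can catch the
package's failures with a single except clause; the CLI maps them to
exit codes (validation/format -> 2, non-segmentable input -> 3).
"""


class FetclustError(Exception):
    """Base class for all package errors."""


class FormatError(FetclustError, ValueError):
    """An on-disk artifact does not match the expected format."""


class ValidationError(FetclustError, ValueError):
    """A value or record violates a domain invariant."""


class GeometryError(FetclustError, ValueError):
    """Two volumes that must share a voxel grid do not."""


class NonSegmentableError(FetclustError, RuntimeError):
    """The Z-score map contains no supra-threshold cluster large enough
    to delineate a tumor; the scan is flagged and excluded downstream."""
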