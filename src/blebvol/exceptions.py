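"""Exception hierarchy.

All package-specific failures derive from :class:`BlebvolError` so callers
(and the CLI, which maps them to exit code 3) can catch one base class.
"""


class BlebvolError(Exception):
    """Base class for all blebvol errors."""


class FormatError(BlebvolError):
    """A file is missing, malformed, or lacks required sidecar metadata."""


class ShapeError(BlebvolError):
    """An array payload has the wrong dimensionality or extents."""


class InvariantError(BlebvolError):
    """A data-type invariant is violated (e.g. upper_z > lower_z)."""


class GeometryError(BlebvolError):
    """A requested phantom geometry does not fit the scan field."""


class AmbiguityError(BlebvolError):
    """Zero or multiple candidate structures where exactly one is required."""


class InsufficientDataError(BlebvolError):
    """Too few subjects/repeats for the requested statistic."""


class DegenerateDataError(BlebvolError):
    """Data with zero variance (or similar) where a test is undefined."""


class DesignError(BlebvolError):
    """A measurement series does not match the declared paired/repeated design."""
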