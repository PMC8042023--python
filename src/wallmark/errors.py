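"""Exception hierarchy shared across modules."""


class WallmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WallmarkError):
    """Invalid configuration value (named in the message)."""


class PlacementError(WallmarkError):
    """Landmark placed outside the allowed axial span."""


class StateError(WallmarkError):
    """Operation invoked on a cell in the wrong state (e.g. division before
    the trigger length is reached)."""


class SegmentationError(WallmarkError):
    """Cell segmentation failed (blank frame, multiple cells, ...)."""


class GeometryError(WallmarkError):
    """Contour/midline geometry is degenerate or too small."""


class NonIdentifiableError(WallmarkError):
    """Changepoint fit has no information on one side of every candidate."""


class DomainError(WallmarkError):
    """Input outside the mathematical domain of an operation."""


class UndefinedPointError(DomainError):
    """Map evaluated at a point where it is undefined (N_y = 0)."""


class SchemaError(WallmarkError):
    """Table does not match the declared column schema."""
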