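"""Exception hierarchy for the airwaymorph pipeline."""


class AirwayMorphError(Exception):
    """Base class for all package errors."""


class MeshFormatError(AirwayMorphError):
    """STL file is unreadable, truncated or empty."""


class NonWatertightError(AirwayMorphError):
    """An operation requiring a closed surface received an open mesh."""

    def __init__(self, message: str, boundary_edges: int = 0):
        super().__init__(message)
        self.boundary_edges = boundary_edges


class DegenerateGeometryError(AirwayMorphError):
    """Input geometry is degenerate (collinear landmarks, empty crop, ...)."""


class LandmarkError(AirwayMorphError):
    """Missing or mismatched landmark labels."""

    def __init__(self, message: str, missing: tuple = ()):
        super().__init__(message)
        self.missing = tuple(missing)


class ConvergenceError(AirwayMorphError):
    """Iterative registration failed to find correspondences / converge."""


class StatisticsError(AirwayMorphError):
    """Invalid input to a statistical routine (single class, n too small)."""
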