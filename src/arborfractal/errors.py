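"""Exception hierarchy for arborfractal.

All errors raised by the package derive from :class:`ArborFractalError` so
callers can catch everything from this library with a single except clause.
"""


class ArborFractalError(Exception):
    """Base class for all arborfractal errors."""


class SWCParseError(ArborFractalError):
    """A line of an SWC (or segment-list) file could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructuralError(ArborFractalError):
    """The node/parent topology is not a forest (cycle, orphan parent, ...)."""


class EmptyArborError(ArborFractalError):
    """An operation requiring dendrite nodes received none."""


class DegenerateGeometryError(ArborFractalError):
    """Zero-length segment, coincident points, or similar degenerate input."""


class ParameterError(ArborFractalError):
    """An invalid parameter value (non-positive ruler length, bad range...)."""


class InsufficientDataError(ArborFractalError):
    """Too few points/bins/rows inside the requested fit range."""


class RangeError(ArborFractalError):
    """No shared normalized scale range across branches."""

    def __init__(self, message: str, spans=None):
        self.spans = spans
        super().__init__(message)


class DivergentDimensionError(ArborFractalError):
    """Tortuosity slope S >= 1 maps outside the valid dimension range."""


class DegenerateHullError(ArborFractalError):
    """Convex hull of a coplanar/collinear point set is not 3-dimensional."""
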