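"""Exception types raised across the package."""


class GenespinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GenespinError, ValueError):
    """A model, schedule, or generator parameter violates its constraint."""


class DimensionError(GenespinError, ValueError):
    """A spin configuration does not match the network it is paired with."""


class ConventionError(GenespinError, ValueError):
    """An operation received a spin configuration in the wrong convention."""


class MissingMetadataError(GenespinError, ValueError):
    """The network lacks generator metadata (m) required by the operation."""


class EdgeListParseError(GenespinError, ValueError):
    """A malformed line was encountered while reading an edge-list file."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class SelfLoopError(GenespinError, ValueError):
    """A self-loop edge (i, i) was supplied; the model requires simple graphs."""


class SizeCapError(GenespinError, ValueError):
    """Exact enumeration was requested for a graph above the hard size cap."""


class EmptyNetworkError(GenespinError, ValueError):
    """A sampler was run on a network with zero nodes."""


class NoTransitionError(GenespinError, RuntimeError):
    """A critical-field estimate was requested from a sweep that never crosses 1/2."""


class SingularApproximationError(GenespinError, ArithmeticError):
    """The high-temperature closed form was evaluated at its singular point."""
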