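"""Exception hierarchy.

All package errors derive from :class:`PathdynError` so callers can catch a
single base class; most also derive from the matching builtin (``ValueError``,
``RuntimeError``) so they behave sensibly in generic code.
"""


class PathdynError(Exception):
    """Base class for all pathdyn errors."""


class SchemaError(PathdynError, ValueError):
    """A file or table does not match the expected multiomics schema."""


class ValidationError(PathdynError, ValueError):
    """Data violates an invariant (negative concentration, unsorted times...)."""


class InvalidParameterError(PathdynError, ValueError):
    """A model parameter is outside its admissible domain."""


class InsufficientPointsError(PathdynError, ValueError):
    """Too few time points for the requested operation."""


class DegenerateGridError(PathdynError, ValueError):
    """The time grid contains duplicate values."""


class ConfigurationError(PathdynError, ValueError):
    """Invalid search-space / experiment configuration."""


class SimulationError(PathdynError, RuntimeError):
    """The kinetic integrator failed."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class DivergenceError(PathdynError, RuntimeError):
    """A learned-dynamics integration blew past the divergence ceiling."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class ExtrapolationError(PathdynError, ValueError):
    """An interpolant was queried outside its observed span."""


class FitFailureError(PathdynError, RuntimeError):
    """Global optimisation failed to produce any finite candidate."""


class IncompatibilityError(PathdynError, ValueError):
    """Two series do not share a time span or species set."""


class DegenerateResponseError(PathdynError, ValueError):
    """The response vector carries no variance to regress against."""
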