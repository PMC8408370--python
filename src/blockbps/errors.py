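"""Exception hierarchy shared across the package."""


class BlockBPSError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BlockBPSError, ValueError):
    """A model or sampler parameter is outside its admissible domain."""


class ShapeError(BlockBPSError, ValueError):
    """Array arguments have inconsistent shapes."""


class StrategyError(BlockBPSError, ValueError):
    """A blocking strategy violates its invariants (e.g. does not cover the grid)."""


class PartitionError(BlockBPSError, ValueError):
    """A partition of a blocking strategy violates the disjointness assumption."""


class BoundViolationError(BlockBPSError, RuntimeError):
    """A true event rate exceeded its Poisson thinning bound.

    Raised hard (never silently accepted): it indicates an invalid bound,
    which would bias the sampler's event-time distribution.
    """


class DegenerateReflectionError(BlockBPSError, ArithmeticError):
    """Reflection requested at a point where the block gradient vanishes."""


class NumericalConditioningError(BlockBPSError, ArithmeticError):
    """A covariance matrix lost positive definiteness during filtering."""
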