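"""Exception hierarchy used across the package."""


class TractshiftError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(TractshiftError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(TractshiftError, ValueError):
    """A file's content is inconsistent with what was expected."""


class ResourceError(TractshiftError, RuntimeError):
    """A requested computation would exceed a configured resource cap."""


class StateError(TractshiftError, RuntimeError):
    """An operation was applied to an object in the wrong state."""


class UnsupportedOperationError(TractshiftError, TypeError):
    """The operation is not defined for this kind of input."""


class UndefinedStatisticError(TractshiftError, ValueError):
    """The requested statistic is undefined for the given inputs."""


class FoldingError(TractshiftError, RuntimeError):
    """A surface warp folded (flipped triangle orientation)."""
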