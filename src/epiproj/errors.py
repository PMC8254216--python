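"""Exception types shared across the package."""


class EpiprojError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EpiprojError, ValueError):
    """A parameter value violates its contract (e.g. even filter window)."""


class InvalidInputError(EpiprojError, ValueError):
    """Input data violates its contract (e.g. mismatched shapes, empty stack)."""


class DegenerateGeometryError(EpiprojError, ValueError):
    """A geometric operation received degenerate input (e.g. collinear vertices)."""


class StackIOError(EpiprojError, IOError):
    """A stack file could not be read or written."""
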