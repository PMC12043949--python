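"""Typed exceptions shared across the pipeline stages."""


class NucleomechError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NucleomechError, ValueError):
    """A generator or fit was given a physically meaningless parameter."""


class InvalidGeometryError(NucleomechError, ValueError):
    """A geometric construction (ellipsoid, landmark set, rotation) is degenerate."""


class DataError(NucleomechError, ValueError):
    """Input data violates a documented precondition."""


class SchemaError(DataError):
    """A table is missing columns, has extra columns, or holds non-numeric cells."""

    exit_code = 2


class ShapeError(DataError):
    """Array shapes or frame grids do not match."""


class SegmentationFailure(NucleomechError, RuntimeError):
    """Thresholding produced an empty foreground."""


class DegenerateInputError(NucleomechError, ValueError):
    """An operation was reduced to an empty or zero-measure domain."""


class ConvergenceError(NucleomechError, RuntimeError):
    """A nonlinear fit failed on every start of the multi-start grid."""

    exit_code = 3

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual
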