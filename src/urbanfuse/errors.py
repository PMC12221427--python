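"""Exception hierarchy for the land-cover fusion pipeline."""


class UrbanFuseError(Exception):
    """Base class for all package errors."""


class GridError(UrbanFuseError):
    """Invalid raster geometry (non-positive cell size, empty grid, ...)."""


class AlignmentError(UrbanFuseError):
    """Input rasters do not share an aligned grid in strict mode."""


class CodeError(UrbanFuseError):
    """A class code is unregistered or a raw code is undeclared."""


class FormatError(UrbanFuseError):
    """A file does not meet the declared format contract."""


class SamplingError(UrbanFuseError):
    """A stratified sampling request cannot be satisfied."""


class MatrixError(UrbanFuseError):
    """A confusion matrix is malformed or degenerate."""
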