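"""Exception hierarchy shared across the pipeline.

Format/IO problems and computation problems are kept distinct so the CLI
can map them to stable exit codes (2 and 3 respectively).
"""


class LeafPolError(Exception):
    """Base class for all leafpol errors."""


class ParameterError(LeafPolError, ValueError):
    """A specification or configuration value is out of its valid domain."""


class DimensionError(LeafPolError, ValueError):
    """Array shapes or grids are inconsistent."""


class GeometryError(LeafPolError, ValueError):
    """A traced polygon is degenerate or invalid."""


class FlatCellError(LeafPolError, ArithmeticError):
    """Peak and valley heights coincide; the cap aspect ratio is undefined.

    Mirrors the exclusion of unmeasurable cells from sample averages rather
    than returning an infinite ratio.
    """


class NormalizationError(LeafPolError, ValueError):
    """Polarizer-transmittance reference too small over the required window."""


class FeatureWavelengthError(LeafPolError, ValueError):
    """Wavelength grid does not cover a required feature wavelength."""


class FitError(LeafPolError, RuntimeError):
    """Discriminant model could not be estimated (small or singular class)."""


class SplitError(LeafPolError, RuntimeError):
    """A train/test partition satisfying the class-presence constraint failed."""


class EvaluationError(LeafPolError, RuntimeError):
    """Too many Monte-Carlo runs were skipped to report aggregate rates."""


class FormatError(LeafPolError, ValueError):
    """An on-disk artifact does not match its declared layout."""


class PipelineError(LeafPolError, RuntimeError):
    """Every sample in a batch failed a pipeline stage."""
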