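"""Exception types shared across the pipeline."""


class GutfermError(ValueError):
    """Base class for all gutferm validation and computation errors."""


class SchemaError(GutfermError):
    """A table is missing required columns or has a malformed header."""


class ValidationError(GutfermError):
    """A table parsed but violates an invariant (range, duplicates, coverage)."""


class DegenerateCurveError(GutfermError):
    """A standard curve cannot be fit (e.g. all calibration points at one x)."""


class UndefinedRatioError(GutfermError):
    """A ratio's denominator is zero or absent."""
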