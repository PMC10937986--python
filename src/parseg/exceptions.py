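"""Exception types raised by parseg."""


class ParsegError(Exception):
    """Base class for all parseg errors."""


class ImageFormatError(ParsegError):
    """An input raster could not be interpreted (channels, dtype, size)."""


class DimensionMismatchError(ParsegError):
    """Image and mask (or threshold map) dimensions disagree."""


class StratificationError(ParsegError):
    """A label class is too small to stratify over the requested subsets."""


class DegenerateSampleError(ParsegError):
    """A sample or split lacks the label diversity needed for validation."""


class ThresholdError(ParsegError):
    """A threshold estimator failed (unknown method, non-bimodal histogram)."""


class GridError(ParsegError):
    """An invalid sample-size grid was requested."""


class CurveFitError(ParsegError):
    """Too few points, or degenerate values, for the consistency curve."""
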