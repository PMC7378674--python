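"""Exception types raised across the pipeline."""


class ZoneLVQError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(ZoneLVQError):
    """Raster input has a channel layout the pipeline cannot interpret."""


class DimensionMismatchError(ZoneLVQError):
    """Array shapes are incompatible (zone grid vs image, feature vs prototype)."""


class DegenerateImageError(ZoneLVQError):
    """A binarized image contains no white pixels, so zone features are undefined."""


class MissingClassError(ZoneLVQError):
    """A training set lacks samples for one of the required classes."""


class LabelingError(ZoneLVQError):
    """A truth or prediction label is outside the declared class set."""


class EmptyEvaluationError(ZoneLVQError):
    """An evaluation was requested over zero images."""


class ModelFormatError(ZoneLVQError):
    """A persisted model file is malformed or incomplete."""


class PhantomSpecError(ZoneLVQError):
    """A synthetic phantom specification is geometrically invalid."""
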