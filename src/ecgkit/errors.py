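"""Exception hierarchy shared across the package."""


class EcgKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EcgKitError):
    """A file could not be parsed as the declared format."""


class LeadLookupError(EcgKitError, KeyError):
    """A requested lead name is not present in a record."""


class ParameterError(EcgKitError, ValueError):
    """A parameter is outside its admissible range."""


class LengthError(EcgKitError, ValueError):
    """An input signal is too short for the requested operation."""


class NumericError(EcgKitError):
    """A numerical procedure diverged or became unstable."""


class DetectionError(EcgKitError):
    """Fiducial detection could not produce any beats."""


class LabelingError(EcgKitError):
    """Annotations do not cover the material being labeled."""


class FitError(EcgKitError, ValueError):
    """A model cannot be fit on the given data."""


class DataError(EcgKitError, ValueError):
    """Feature data violates a precondition (non-finite, single class, ...)."""


class SplitError(EcgKitError, ValueError):
    """A train/test or CV split cannot be formed."""
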