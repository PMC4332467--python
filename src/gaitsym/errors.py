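"""Exception hierarchy for gaitsym.

Everything raised on purpose derives from :class:`GaitSymError` so callers can
catch the package's own failures without swallowing programming errors.
"""


class GaitSymError(Exception):
    """Base class for all gaitsym errors."""


class FormatError(GaitSymError):
    """A file does not follow the declared CSV dialect (missing column, bad token)."""


class ParseError(FormatError):
    """A cell could not be parsed; the message carries the offending row."""


class IntegrityError(GaitSymError):
    """Data violates a uniqueness or consistency constraint."""


class DomainError(GaitSymError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class EmptyStanceError(GaitSymError):
    """No sample of a trial reaches the stance-detection threshold."""


class TooShortError(GaitSymError):
    """A stance segment is too short to interpolate."""


class ExtractionError(GaitSymError):
    """Discrete gait parameters cannot be extracted (non-M-shaped curve)."""


class FitError(GaitSymError):
    """A model fit received unusable input."""


class DegenerateDataError(FitError):
    """Input has zero variance where variability is required."""


class DegenerateVarianceError(DomainError):
    """Paired differences are constant and nonzero: the t statistic diverges."""


class DimensionError(GaitSymError, ValueError):
    """Vector lengths or feature dimensions do not match."""


class LabelError(GaitSymError):
    """Class labels are unusable (a class is absent or not in {-1, +1})."""


class FoldError(GaitSymError):
    """A cross-validation fold assignment cannot satisfy the balance constraints."""


class ReportError(GaitSymError):
    """A symmetry report cannot be built from the data provided."""


class GeneratorError(GaitSymError):
    """Synthetic-curve parameters are inconsistent with an M-shaped waveform."""
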