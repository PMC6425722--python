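"""Exception hierarchy for entrokit.

Every error raised by the library derives from :class:`EntrokitError`, so the
analysis engine and the CLI can catch domain failures without swallowing
programming errors.
"""


class EntrokitError(Exception):
    """Base class for all entrokit domain errors."""


class DegenerateSeriesError(EntrokitError):
    """A statistic needed for normalization or tolerance resolution is
    undefined on this series (zero standard deviation or zero range)."""


class TooShortSeriesError(EntrokitError):
    """The series has fewer samples than the embedding requires."""


class GapRangeError(EntrokitError):
    """A gap interval extends past the end of the series."""


class MalformedGapError(EntrokitError):
    """A gap interval is syntactically invalid (start > end, non-integer,
    index < 1, or a row with the wrong number of columns)."""


class DimensionMismatchError(EntrokitError):
    """Two vectors of unequal dimension were compared."""


class InsufficientVectorsError(EntrokitError):
    """Fewer than two valid embedded vectors are available."""


class InsufficientDataError(EntrokitError):
    """No complete motif / not enough pairwise distances to estimate a
    distribution."""


class NonNormalizedDistributionError(EntrokitError):
    """A probability vector does not sum to one (or has negative mass)."""


class GuardRefusalError(EntrokitError):
    """The long-recording memory guard refused a whole-series analysis."""


class WindowTooLongError(EntrokitError):
    """Requested window length exceeds the series length."""


class InvalidOverlapError(EntrokitError):
    """Window overlap leaves a step smaller than one sample."""


class SignalParseError(EntrokitError):
    """A signal / gap / list file failed to parse; message cites the line."""


class EmptyFileError(SignalParseError):
    """A signal file contained no samples."""


class EmptyListError(EntrokitError):
    """A batch list file contained no recording names."""


class InvalidParameterError(EntrokitError):
    """A parameter is outside its documented domain."""
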