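"""Exception hierarchy for blastopol.

Every contract violation raises a subclass of :class:`BlastopolError`, so
callers can catch one base type at pipeline level while tests can assert
the precise failure mode.
"""


class BlastopolError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BlastopolError, ValueError):
    """Invalid simulation/detection/run configuration."""


class FormatError(BlastopolError, ValueError):
    """Input file does not match the expected layout (axes, columns)."""


class EmptyProfileError(BlastopolError):
    """A cell has no contact-free boundary (fully enclosed by neighbors)."""


class InvalidMeasurementError(BlastopolError, ValueError):
    """An intensity measurement violates its precondition (e.g. Icyto <= 0)."""


class InvalidInputError(BlastopolError, ValueError):
    """Generic precondition failure on operation inputs."""


class UndefinedRatioError(BlastopolError):
    """A group-ratio is requested for an embryo lacking one of the groups."""


class IncompleteTraceError(BlastopolError):
    """An intensity trace does not cover the required event frame."""


class NoCandidateError(BlastopolError):
    """Profile too short to host any window in the configured length range."""


class MissingInputError(BlastopolError):
    """A required mask or table is empty or absent."""


class NotAdjacentError(BlastopolError):
    """Two masks share no contact interface."""


class InvalidShapeError(BlastopolError):
    """Mask is degenerate for the requested geometric measurement."""


class InsufficientDepthError(BlastopolError):
    """3-D measurement requested on a mask spanning fewer than two z-slices."""


class IncompleteTrackError(BlastopolError):
    """Track ends before the stage the measurement is defined on."""


class UnresolvableClassError(BlastopolError):
    """Polarity class cannot be decided (e.g. missing IEA at onset)."""


class AnomalousDivisionError(BlastopolError):
    """Division outcome outside the symmetric/asymmetric dichotomy."""


class DegenerateTestError(BlastopolError):
    """A statistical test is undefined for the given data (e.g. pooled p in {0,1})."""


class InsufficientDataError(BlastopolError):
    """Too few observations for the requested statistical procedure."""
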