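"""Exception hierarchy.

Every error raised by the package derives from :class:`SomnarchError`, so
callers can catch one type at a pipeline boundary while tests can assert on
the specific failure mode.
"""


class SomnarchError(Exception):
    """Base class for all package errors."""


class ValidationError(SomnarchError, ValueError):
    """A parameter or configuration value violates its contract."""


class FormatError(SomnarchError):
    """A file does not conform to its declared format."""


class ChannelNotFoundError(FormatError):
    """A required channel label is absent from a recording file."""


class HypnogramParseError(FormatError):
    """A hypnogram file contains an unknown state token or bad row."""


class EmptyHypnogramError(FormatError):
    """A hypnogram file contains no epochs."""


class UnsupportedOperationError(SomnarchError):
    """The requested operation is outside the supported envelope."""


class NoValidEpochsError(SomnarchError):
    """Every epoch was excluded (e.g. all marked as artifact)."""


class NoNremsError(SomnarchError):
    """The hypnogram contains no NREMS epochs; spindle detection undefined.

    Distinct from an empty detection result, which is a valid outcome.
    """


class UndefinedMetricError(SomnarchError):
    """A summary statistic is undefined for the given input (e.g. median
    bout duration of a state that never occurs)."""


class ConfigMismatchError(SomnarchError):
    """Two runs being compared were produced under incompatible configs."""


class PipelineError(SomnarchError):
    """A pipeline stage failed; the message names the stage."""

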