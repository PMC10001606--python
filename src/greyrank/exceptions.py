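"""Exception hierarchy for greyrank.

Every error raised by the package derives from :class:`GreyRankError`, so
callers (and the CLI) can catch one base class while tests discriminate on
the specific failure mode.
"""


class GreyRankError(Exception):
    """Base class for all greyrank errors."""


class ConfigurationError(GreyRankError):
    """A required column, group, or option is missing or inconsistent."""


class PanelParseError(GreyRankError):
    """A cell in the input panel could not be parsed as a number."""


class AlignmentError(GreyRankError):
    """Sequences (or panel rows) do not share a common year axis."""


class LengthError(GreyRankError):
    """A sequence is too short for the requested operation."""


class DegenerateSequenceError(GreyRankError):
    """A normalization divisor (mean or first value) is zero."""


class DomainError(GreyRankError):
    """A degree or weight lies outside its admissible interval."""


class ResamplingError(GreyRankError):
    """Bootstrap resampling kept producing rank-deficient designs."""
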