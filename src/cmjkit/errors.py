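"""Exception hierarchy for cmjkit.

All package-specific failures derive from :class:`CmjkitError` so callers can
catch a single base class when batch-processing trials.
"""


class CmjkitError(Exception):
    """Base class for all cmjkit errors."""


class SchemaError(CmjkitError):
    """A landmark table does not satisfy the 14-landmark schema."""


class TrajectoryParseError(CmjkitError):
    """A trajectory file could not be parsed (bad header, non-numeric cell...)."""


class GapError(CmjkitError):
    """A trajectory gap cannot be filled (too long, or at a series edge)."""


class DetectionError(CmjkitError):
    """Jump-event detection failed (flat trace, ordering violation...)."""


class AmbiguousTrialError(DetectionError):
    """The trial contains more than one flight excursion."""


class NoFlightError(DetectionError):
    """No supra-threshold toe excursion: the trial contains no flight phase."""


class VariableError(CmjkitError):
    """Extracted jump variables violate a structural invariant."""


class StatsError(CmjkitError):
    """An agreement/reliability statistic is undefined for the given sample."""
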