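"""Exception hierarchy.

All toolkit errors derive from :class:`ProphikitError` so callers can catch
one base class; subclasses distinguish the failure modes the pipeline treats
differently (admission vs. validation vs. internal consistency).
"""


class ProphikitError(Exception):
    """Base class for all toolkit errors."""


class AdmissionError(ProphikitError):
    """Assembly rejected by a corpus-admission rule (e.g. too many contigs)."""


class ValidationError(ProphikitError):
    """Input violates a documented precondition."""


class ConfigurationError(ProphikitError):
    """A required database or configuration item is missing or malformed."""


class AnnotationError(ProphikitError):
    """A referenced annotation (e.g. a cluster label) is absent."""


class GroupingError(ProphikitError):
    """Fragments passed together do not share a common reference."""


class SpliceError(ProphikitError):
    """Fragments cannot be ordered into a collinear chain."""


class ConsistencyError(ProphikitError):
    """A sequence-level invariant does not hold (e.g. att core not at ends)."""
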