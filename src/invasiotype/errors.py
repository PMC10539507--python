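"""Exception hierarchy.

Every error raised by this package derives from :class:`InvasiotypeError`
and from the most fitting builtin, so callers can catch either.
"""


class InvasiotypeError(Exception):
    """Base class for all package errors."""


class ParameterError(InvasiotypeError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class DomainError(InvasiotypeError, ValueError):
    """An input lies outside the mathematical domain of a formula."""


class AlignmentError(InvasiotypeError, ValueError):
    """Two tables that must share sample identifiers do not overlap."""


class InsufficientDataError(InvasiotypeError, ValueError):
    """Too few observations to carry out the requested computation."""


class AmbiguityError(InvasiotypeError, ValueError):
    """The input admits no unique answer (e.g. all values identical)."""


class MissingSetError(InvasiotypeError, KeyError):
    """A gene set has no member in the expression universe."""


class DegenerateSetError(InvasiotypeError, ValueError):
    """A gene set covers the entire gene universe; enrichment is undefined."""


class MappingError(InvasiotypeError, KeyError):
    """A gene-set name has no transcription-factor attribution."""


class EmptyResultError(InvasiotypeError, ValueError):
    """Every input unit was dropped; nothing remains to report."""


class StratificationError(InvasiotypeError, ValueError):
    """Score-quantile stratification would produce an empty group."""


class ValidationError(InvasiotypeError, ValueError):
    """A pipeline configuration failed validation (bad path or value)."""
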