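"""Exception hierarchy for reeftrack."""


class ReeftrackError(Exception):
    """Base class for all reeftrack errors."""


class SchemaError(ReeftrackError):
    """An input table is missing required columns or has an unusable layout."""


class ValidationError(ReeftrackError):
    """An input table violates a structural invariant (e.g. overlapping
    receiver deployments, inverted active intervals, duplicate keys)."""


class MalformedDataError(ReeftrackError):
    """Too many rows of an input file failed row-level parsing."""


class UndefinedMetricError(ReeftrackError):
    """A metric's denominator is zero or its preconditions are not met."""


class NoEventsError(ReeftrackError):
    """A summary was requested for a stratum that contains no events/moves."""
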