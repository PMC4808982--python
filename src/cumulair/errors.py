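"""Exception hierarchy for cumulair.

All package errors derive from :class:`CumulairError` so callers can catch
one base class at pipeline boundaries.
"""


class CumulairError(Exception):
    """Base class for all cumulair errors."""


class SchemaError(CumulairError):
    """A tabular input file does not conform to its schema (bad column,
    unparseable cell); carries file name and, where known, the row."""


class ValidationError(CumulairError):
    """A value violates a domain-type invariant (non-positive concentration,
    mobility row not summing to one, ...)."""


class CrossRefError(CumulairError):
    """An identifier in one input does not resolve against another
    (unknown unit in a mobility row, unknown station in a daily series)."""


class ConfigurationError(CumulairError):
    """A run configuration or simulation specification is inconsistent."""


class StationCoverageError(CumulairError):
    """A cluster containing spatial units contains no monitoring station,
    leaving those units without an index monitor."""


class ExtrapolationError(CumulairError):
    """A back-cast was requested beyond the configured extrapolation
    horizon."""


class MissingExposureError(CumulairError):
    """An exposure value needed with positive residence probability is
    missing (unit/year cell, or the outside-area series)."""
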