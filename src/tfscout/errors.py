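"""Exception hierarchy shared across the pipeline.

Each class maps to a distinct CLI exit code so callers can tell input
problems apart from internal consistency violations and numeric failures.
"""


class TfscoutError(Exception):
    """Base class for all tfscout errors."""

    exit_code = 1


class InputError(TfscoutError):
    """Unreadable, malformed, or wrong-alphabet user input."""

    exit_code = 2


class ParameterError(TfscoutError):
    """Invalid parameter value (out of range, unknown dialect, ...)."""

    exit_code = 2


class ConsistencyError(TfscoutError):
    """Cross-file or cross-object identifiers do not agree."""

    exit_code = 3


class CoordinateError(ConsistencyError):
    """A genomic region falls outside its contig or is degenerate."""


class NumericError(TfscoutError):
    """Numeric failure: non-finite loss, non-positive self score, ..."""

    exit_code = 4


class EmptyDatabaseError(TfscoutError):
    """Curation removed every record."""

    exit_code = 2


class DegenerateTrainingError(TfscoutError):
    """Training set cannot support classification (e.g. one family)."""

    exit_code = 2


class UndefinedMetricError(TfscoutError):
    """Metric denominator is zero where the metric is undefined."""

    exit_code = 4


class IncompatibilityError(TfscoutError):
    """Model bundle is corrupt or from an incompatible version."""

    exit_code = 2
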