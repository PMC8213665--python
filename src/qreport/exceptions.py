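"""Exception hierarchy for qreport.

All validation problems raise :class:`QReportError` subclasses so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class QReportError(Exception):
    """Base class for all qreport errors."""


class SchemaError(QReportError):
    """A required column or field is missing from an input table."""


class ValidationError(QReportError):
    """A row or record violates a domain invariant (names the offender)."""


class DuplicateRecordError(ValidationError):
    """The same (rater, scan, condition) episode appears more than once."""


class DegenerateDesignError(QReportError):
    """The regression design matrix is rank deficient (e.g. a single age)."""


class DegenerateVarianceError(QReportError):
    """Residual variance is zero; percentiles are undefined."""
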