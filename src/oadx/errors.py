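"""Exception hierarchy shared across the package."""


class OadxError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OadxError, ValueError):
    """An input is outside the mathematical domain of an operation
    (e.g. a ratio with a zero denominator, a negative concentration)."""


class SpecimenValidationError(OadxError, ValueError):
    """A specimen record violates the data contract (missing or
    inconsistent fields, bad censor flags, unknown labels)."""


class UndefinedMetricError(OadxError, ZeroDivisionError):
    """A diagnostic metric is requested whose denominator is zero."""


class DegenerateDataError(OadxError, ValueError):
    """The data admit no informative test (e.g. all values identical
    in a median test, a single-class ROC input)."""


class SchemaError(OadxError, ValueError):
    """A tabular input file does not conform to the expected schema."""
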