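"""Exception hierarchy shared across the package."""


class BeliefUpdateError(Exception):
    """Base class for all package errors."""


class ValidationError(BeliefUpdateError, ValueError):
    """An input value violates a documented range or coding rule."""


class SchemaError(BeliefUpdateError, ValueError):
    """A tabular input file is missing columns or contains malformed rows."""


class DegenerateDataError(BeliefUpdateError, ValueError):
    """Data are formally valid but carry no usable variation (e.g. zero variance)."""


class UnscorableSubjectError(BeliefUpdateError, ValueError):
    """A subject lacks the good and bad news trials needed to compute an update bias."""
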