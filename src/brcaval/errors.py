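"""Exception hierarchy.

Error classes distinguish bad parameters, malformed input schemas,
degenerate statistical inputs and model-fitting failures so callers
(and the CLI exit codes) can react differently to each.
"""


class BrcavalError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BrcavalError, ValueError):
    """A numeric or structural argument violates its precondition."""


class SchemaError(BrcavalError, KeyError):
    """Input data refer to an unknown category, country or column."""


class DegenerateDataError(BrcavalError, ValueError):
    """A statistic is undefined on this input (single class, no events...)."""


class FittingError(BrcavalError, RuntimeError):
    """A maximum-likelihood fit failed (separation, single-class group)."""
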