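"""Exception hierarchy shared across the pipeline."""


class PMSSAError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PMSSAError, ValueError):
    """Input violates a documented precondition (shape, domain, duplicates)."""


class DegenerateInputError(PMSSAError, ValueError):
    """Input is formally valid but the statistic is undefined on it
    (e.g. every expert ties every item, or a constant vector in a
    rank correlation)."""


class NumericalFailureError(PMSSAError, ArithmeticError):
    """An iterative numerical procedure failed to converge."""


class UnsupportedOrderError(PMSSAError, ValueError):
    """Matrix order outside the tabulated random-index range."""


class SchemaError(PMSSAError, ValueError):
    """A structured artifact (hierarchy JSON, CSV table) violates its schema."""
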