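"""Exception hierarchy shared across the package."""


class TipcaError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(TipcaError):
    """A required column or configuration field is missing or malformed."""


class IntegrityError(TipcaError):
    """Input data violate a dataset invariant (duplicates, negatives, ...)."""


class InsufficientDataError(TipcaError):
    """Too few observations to carry out the requested computation."""


class IntervalError(TipcaError):
    """A time-interval specification is inconsistent with the sampling grid."""


class DegenerateInputError(TipcaError):
    """Input is structurally valid but degenerate (e.g. all-zero loadings)."""
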