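"""Exception hierarchy for survtransport."""


class SurvTransportError(Exception):
    """Base class for all survtransport errors."""


class SchemaError(SurvTransportError):
    """A required column is absent or the schema map is inconsistent."""


class ValidationError(SurvTransportError):
    """A record violates a data-model invariant."""


class FittingError(SurvTransportError):
    """A nuisance model failed to fit (non-convergence, separation, rank deficiency)."""


class EstimationError(SurvTransportError):
    """An estimator could not be evaluated (empty arm, degenerate weights)."""
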