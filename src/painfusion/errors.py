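"""Exception hierarchy for painfusion."""


class PainfusionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PainfusionError):
    """Invalid configuration (cohort sizes, mixing weights, schema keys)."""


class SpecificationError(PainfusionError):
    """Unknown model term, coefficient name, or coarsening coverage gap."""


class InterpolationError(PainfusionError):
    """Too few observed points to interpolate a patient's weekly series."""


class DegenerateInputError(PainfusionError):
    """Zero-variance or otherwise degenerate input to a statistic."""


class SingularFitError(PainfusionError):
    """Rank-deficient regression design."""


class PredictionError(PainfusionError):
    """Missing input required to roll a trajectory forward."""
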