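"""Exception types shared across the package."""


class HazvisError(Exception):
    """Base class for package errors."""


class InvalidInputError(HazvisError, ValueError):
    """An input value violates a precondition (non-finite, wrong shape, ...)."""


class ConfigurationError(HazvisError, ValueError):
    """A configuration value is unusable (bad anchor, bad band count, ...)."""


class DegenerateDesignError(HazvisError, ValueError):
    """A statistical design carries no information (constant predictor,
    single-class outcome, too few trials)."""


class EmptyROIError(HazvisError, ValueError):
    """The region of interest contains no geometry pixels to score."""
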