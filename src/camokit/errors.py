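"""Exception hierarchy shared across the toolkit."""


class CamokitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CamokitError, ValueError):
    """An input object violates a documented invariant."""


class DimensionError(ValidationError):
    """Image or array dimensions are unusable for the requested operation."""


class ConvergenceError(CamokitError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class ModelSpecError(ValidationError):
    """A model design matrix is rank deficient or otherwise unusable."""
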