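"""Exception hierarchy for proacs."""


class ProacsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ProacsError):
    """Invalid configuration (thresholds, mixing proportions, selectors...)."""


class ValidationError(ProacsError):
    """Input data violates a contract (out-of-range response, bad column...)."""


class GridError(ProacsError):
    """Composite grid is incomplete or contains out-of-range images."""


class EstimationError(ProacsError):
    """A numerical estimation routine failed or did not converge."""


class HeywoodError(EstimationError):
    """Inadmissible factor solution: standardized loading >= 1 in magnitude
    (equivalently a negative residual variance)."""

    def __init__(self, message: str, loadings=None):
        super().__init__(message)
        self.loadings = loadings


class JustIdentifiedError(EstimationError):
    """Model has zero degrees of freedom; fit indices are undefined."""
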