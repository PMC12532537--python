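"""Exception hierarchy shared across the package."""


class AdcResponseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AdcResponseError, ValueError):
    """Invalid cohort or pipeline configuration."""


class DomainError(AdcResponseError, ValueError):
    """An argument is outside the domain of an operation."""


class GeometryError(AdcResponseError, ValueError):
    """A lesion cannot be rendered at the requested spacing/extent."""


class ROIPlacementError(AdcResponseError, RuntimeError):
    """No disc of the requested (or fallback) radius fits inside the mask."""


class UndefinedDeltaError(AdcResponseError, ArithmeticError):
    """Percent change is undefined because the pre-treatment value is zero."""
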