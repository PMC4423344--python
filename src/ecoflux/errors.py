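"""Exception hierarchy shared across the pipeline stages."""


class EcofluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(EcofluxError):
    """A configuration value violates its documented constraints."""


class InvalidParameterError(EcofluxError):
    """A model parameter is outside its admissible range."""


class InsufficientDataError(EcofluxError):
    """Too few observations for the requested fit."""


class InsufficientVariationError(InsufficientDataError):
    """The regressor is constant, so a slope cannot be identified."""


class InsufficientBinsError(InsufficientDataError):
    """Fewer than two bins survive the minimum-days rule."""


class FitFailureError(EcofluxError):
    """No candidate model converged; carries per-form diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConvergenceError(EcofluxError):
    """An iterative solver exhausted its iteration budget."""


class DegenerateCurveError(EcofluxError):
    """The curve carries no usable signal (e.g. zero initial slope)."""


class DegenerateInputError(EcofluxError):
    """An input series is identically zero or otherwise contentless."""


class SingularityError(EcofluxError):
    """Evaluation would divide by zero."""


class UndefinedIndexError(EcofluxError):
    """A ratio index is undefined; names the offending field."""

    def __init__(self, field: str):
        super().__init__(f"index undefined: field {field!r} makes the denominator zero")
        self.field = field


class InvalidSignalError(EcofluxError):
    """A sensor signal violates physical constraints (e.g. dT <= 0)."""


class InvalidGeometryError(EcofluxError):
    """Tree geometry is missing or inconsistent."""


class BaselineFailureError(EcofluxError):
    """No zero-flow baseline window qualifies; carries near misses."""

    def __init__(self, message: str, near_misses: list | None = None):
        super().__init__(message)
        self.near_misses = near_misses or []


class ConfigurationError(EcofluxError):
    """A named plug-in (e.g. a sap-flow correction) is not registered."""


class DependencyError(EcofluxError):
    """A pipeline stage was requested without its upstream inputs."""


class SchemaValidationError(EcofluxError):
    """A delimited input table failed schema validation."""
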