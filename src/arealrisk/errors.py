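"""Exception hierarchy shared across the package."""


class ArealRiskError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ArealRiskError):
    """Input table or weights file failed validation."""


class GeometryError(ArealRiskError):
    """Polygon or centroid geometry is missing or invalid."""


class DegenerateInputError(ArealRiskError):
    """Input is structurally valid but statistically degenerate."""


class DomainError(ArealRiskError):
    """Argument outside the mathematical domain of an operation."""
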