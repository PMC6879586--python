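"""Exception hierarchy shared across the package."""


class PorefluxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PorefluxError):
    """Structure/trajectory files are inconsistent or unreadable."""


class AnnotationError(PorefluxError):
    """A structural role cannot be mapped onto atoms unambiguously."""


class GeometryError(PorefluxError):
    """Geometric preconditions are violated (e.g. inverted site bounds)."""


class SchemaError(PorefluxError):
    """Records passed to a tidy writer do not share one schema."""


class ConfigError(PorefluxError):
    """A run configuration contains unknown or out-of-bounds entries."""
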