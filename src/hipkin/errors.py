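"""Exception hierarchy shared across the package."""


class HipkinError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HipkinError):
    """Invalid parameter value (non-positive step, shape mismatch, ...)."""


class FormatError(HipkinError):
    """A file could not be read or violates format expectations."""


class GeometryError(HipkinError):
    """Invalid projection geometry (degenerate axes, source in plane)."""


class NonProjectablePointError(GeometryError):
    """A 3D point lies at or beyond the source plane and cannot be projected."""


class DegenerateConfigurationError(HipkinError):
    """Input point set is degenerate (too few points, coplanar, collinear)."""


class ConstantImageError(HipkinError):
    """An image is constant where a non-constant one is required."""


class InitializationError(HipkinError):
    """Registration metric is undefined at the initial pose."""


class FieldOfViewError(HipkinError):
    """A pose places the object (partly) outside the detector field of view."""


class ConfigError(HipkinError):
    """Configuration file violates the schema."""
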