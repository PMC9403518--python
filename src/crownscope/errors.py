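"""Exception hierarchy shared across the pipeline stages."""


class CrownscopeError(Exception):
    """Base class for all package errors."""


class DimensionError(CrownscopeError, ValueError):
    """Raster or mask shapes are incompatible."""


class ParameterError(CrownscopeError, ValueError):
    """A parameter value is out of its valid range."""


class ConfigurationError(CrownscopeError, ValueError):
    """A configuration is inconsistent (missing band, unknown key, ...)."""


class DataError(CrownscopeError, ValueError):
    """Input data violates a contract (non-binary mask, empty tile set, ...)."""


class UndefinedMetricError(CrownscopeError, ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not 0."""


class PlacementError(CrownscopeError, RuntimeError):
    """Synthetic-scene crown placement failed after bounded retries."""


class FitError(CrownscopeError, RuntimeError):
    """Geometric model fitting failed on a degenerate component."""
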