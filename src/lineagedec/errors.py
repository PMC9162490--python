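"""Exception hierarchy shared across the package."""


class LineagedecError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LineagedecError, ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


class InputError(LineagedecError, ValueError):
    """User-supplied data violates a documented contract (ids, dimensions, ranges)."""


class EmptyResultError(LineagedecError, RuntimeError):
    """An operation removed or excluded everything; nothing remains to analyze."""


class DegenerateFitError(LineagedecError, RuntimeError):
    """A model fit collapsed (e.g. all-zero coefficients) and cannot be interpreted."""
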