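"""Exception types shared across the package."""


class MudflatError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MudflatError, ValueError):
    """Invalid configuration value (non-positive extent, bad fraction, ...)."""


class SpatialError(MudflatError, ValueError):
    """A coordinate falls outside the supported spatial domain."""


class ConsistencyError(MudflatError, ValueError):
    """Inputs that must share provenance (spacing, offsets, keys) disagree."""


class ComparisonError(MudflatError, ValueError):
    """A design comparison violates its fairness contract (unequal n)."""


class DegenerateFieldError(MudflatError, ValueError):
    """The field has no variance; autocorrelation is undefined."""


class ScaleError(MudflatError, ValueError):
    """Too few records at every hierarchical scale for the requested fit."""


class SchemaError(MudflatError, ValueError):
    """A table violates its published schema contract."""
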