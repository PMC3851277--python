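"""Exception hierarchy shared across the package."""


class CellphenoError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CellphenoError, ValueError):
    """A required column is missing or has an unusable dtype."""


class IntegrityError(CellphenoError, ValueError):
    """The table violates a structural invariant (e.g. duplicate keys)."""


class ParseError(CellphenoError, ValueError):
    """A cell value could not be parsed; carries the offending row index."""


class ConfigError(CellphenoError, ValueError):
    """Inconsistent simulation or pipeline configuration."""


class InsufficientDataError(CellphenoError, ValueError):
    """Not enough observations to perform the requested computation."""


class InitializationError(CellphenoError, ValueError):
    """Cell-cycle-bin HMM initialization failed (e.g. an empty bin in strict mode)."""


class NumericalError(CellphenoError, ArithmeticError):
    """Numerical failure (underflow / singular matrix) during model fitting."""


class ModelError(CellphenoError, ValueError):
    """A model cannot be fitted or applied to the given data."""


class UndefinedFingerprintError(CellphenoError, ValueError):
    """A fingerprint was requested for an owner with zero abnormal cells."""


class UndefinedScoreError(CellphenoError, ValueError):
    """The siRNA score is undefined (zero between-set distance)."""
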