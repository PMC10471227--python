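"""Exception hierarchy shared across the package."""


class PhenoswitchError(Exception):
    """Base class for all package errors."""


class ParameterError(PhenoswitchError, ValueError):
    """A model parameter is outside its admissible range."""


class InvalidMotifError(PhenoswitchError, ValueError):
    """A fitness-motif vector violates the motif contract."""


class LandscapeFormatError(PhenoswitchError, ValueError):
    """A tabulated landscape file is malformed.

    Carries the 1-based row number of the offending line when applicable.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class StructuralError(PhenoswitchError, ValueError):
    """Dimension or genotype-set mismatch between model components."""


class DegeneratePopulationError(PhenoswitchError, ArithmeticError):
    """Mean fitness is zero: the whole population has fitness zero."""


class NumericalError(PhenoswitchError, ArithmeticError):
    """A numerical solver failed (e.g. degenerate leading eigenvalue)."""


class ConfigError(PhenoswitchError, ValueError):
    """A run configuration is invalid or refers to missing files."""
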