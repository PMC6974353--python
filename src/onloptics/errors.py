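"""Exception hierarchy shared across the package."""


class OnlOpticsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OnlOpticsError, ValueError):
    """A parameter is outside its physically or numerically valid range."""


class DegenerateInputError(InvalidInputError):
    """The requested quantity is undefined for this input (e.g. a
    zero-contrast sphere has no scattered field to normalize)."""


class NumericalError(OnlOpticsError, ArithmeticError):
    """A series or iteration failed to converge; carries a diagnostic."""


class PackingError(OnlOpticsError, RuntimeError):
    """Requested nucleus packing could not be achieved.

    Attributes
    ----------
    achieved : int
        Number of nuclei successfully placed before giving up.
    """

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class ResourceError(OnlOpticsError, MemoryError):
    """A simulation grid exceeds the configured memory budget."""


class FileFormatError(OnlOpticsError, IOError):
    """A file could not be parsed as the expected format."""


class ConfigError(OnlOpticsError, ValueError):
    """Pipeline configuration failed validation; names the offending field."""
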