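"""Exception hierarchy for the pipeline."""


class TwinEwasError(Exception):
    """Base class for all package errors."""


class ConfigError(TwinEwasError):
    """Invalid simulation or pipeline configuration."""


class InputError(TwinEwasError):
    """Input data violate a precondition (empty matrix, too few pairs...)."""


class CollinearityError(TwinEwasError):
    """A regression design matrix is rank deficient (e.g. constant age)."""


class ConvergenceError(TwinEwasError):
    """An iterative fit failed to converge after all restarts."""


class ParseError(TwinEwasError):
    """A standard-format file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
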