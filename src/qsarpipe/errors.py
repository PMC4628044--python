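"""Exception hierarchy shared across the package."""


class QsarPipeError(Exception):
    """Base class for all package errors."""


class ParseError(QsarPipeError):
    """A structure or table file could not be parsed."""


class MoleculeError(QsarPipeError):
    """A molecule violates an invariant required by an operation."""


class DescriptorError(QsarPipeError):
    """A descriptor could not be computed; carries the descriptor name."""

    def __init__(self, message: str, descriptor: str | None = None):
        super().__init__(message if descriptor is None else f"{descriptor}: {message}")
        self.descriptor = descriptor


class ModelingError(QsarPipeError):
    """Regression / selection failure (rank deficiency, too few rows, ...)."""


class ConfigError(QsarPipeError):
    """Invalid pipeline configuration or CLI input."""
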