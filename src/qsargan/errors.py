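"""Exception hierarchy shared across the pipeline."""


class QsarGanError(Exception):
    """Base class for all package errors."""


class ValidationError(QsarGanError, ValueError):
    """A specification or parameter value is out of its admissible range."""


class SchemaError(QsarGanError, ValueError):
    """Tabular input does not match the expected column schema."""


class LeakageError(QsarGanError, RuntimeError):
    """Synthetic or training rows were found in an evaluation split."""


class DivergenceError(QsarGanError, RuntimeError):
    """Adversarial training produced a non-finite loss."""
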