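"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class MissingDataError(RuntimeError):
    """Requested data (e.g. an excerpt window) is not covered by the input."""


class FormatError(RuntimeError):
    """An input file does not conform to a supported dialect."""


class ConfigError(RuntimeError):
    """A configuration document fails schema validation."""


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss; carries the partial history."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history
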