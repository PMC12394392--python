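"""Exception types shared across the package."""


class LaseNetError(Exception):
    """Base class for package errors."""


class InvalidParameterError(LaseNetError, ValueError):
    """A cognitive-model parameter is missing, unknown, or out of bounds."""


class InvalidInputError(LaseNetError, ValueError):
    """An operation received a malformed input (empty vector, bad range)."""


class SchemaError(LaseNetError, ValueError):
    """Data does not conform to the expected session/dataset schema."""


class ConfigError(LaseNetError, ValueError):
    """A configuration object or file is inconsistent."""


class UnsupportedOperationError(LaseNetError, ValueError):
    """The requested operation is not defined for this model."""


class TrainingDivergedError(LaseNetError, RuntimeError):
    """Network training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class FilterDegeneracyError(LaseNetError, RuntimeError):
    """All particle weights vanished (impossible observation under theta)."""

    def __init__(self, trial: int):
        self.trial = trial
        super().__init__(f"all particle weights are zero at trial {trial}")


class EMFailureError(LaseNetError, RuntimeError):
    """EM produced a non-finite likelihood."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"non-finite log-likelihood at EM iteration {iteration}")
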