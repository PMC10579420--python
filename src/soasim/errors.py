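"""Exception hierarchy for soasim."""


class SoasimError(Exception):
    """Base class for all soasim errors."""


class ConfigurationError(SoasimError, ValueError):
    """Invalid configuration (ranges, lesion parameters, hyperparameters)."""


class EncodingError(SoasimError, ValueError):
    """A task event cannot be placed inside the sequence time window."""


class EvaluationError(SoasimError, ValueError):
    """A summary statistic cannot be computed (missing condition, bad bins)."""


class TrainingDivergenceError(SoasimError, RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged at epoch {epoch}")
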