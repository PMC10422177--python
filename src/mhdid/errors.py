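"""Exception hierarchy for the mhdid pipeline."""


class MhdidError(Exception):
    """Base class for all mhdid errors."""


class ConfigError(MhdidError):
    """Invalid configuration (windows, probabilities, effect maps, ...)."""


class DataError(MhdidError):
    """Malformed input data (duplicate epochs, missing adoption months, ...)."""


class EstimationError(MhdidError):
    """Estimation cannot proceed (rank deficiency, empty subgroup, too few clusters)."""


class ConvergenceError(EstimationError):
    """Iterative demeaning failed to converge within the sweep budget."""

    def __init__(self, message: str, sweeps: int, max_delta: float):
        super().__init__(message)
        self.sweeps = sweeps
        self.max_delta = max_delta
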