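"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A constructor or generator argument is out of its valid domain."""


class InvalidInputError(ValueError):
    """Runtime data handed to an operation violates its preconditions."""


class NoValidProbeError(RuntimeError):
    """No adjacent transposition can alter the sequence (constant sequence)."""


class DesignInfeasibleError(RuntimeError):
    """Constrained trial-order sampling failed within the retry budget."""


class UndefinedStatisticError(ValueError):
    """Too few observations (or a degenerate configuration) to define the statistic."""


class SingularDesignError(ValueError):
    """A GLM design matrix is rank deficient; carries the offending columns."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)
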