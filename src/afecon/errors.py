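"""Exception hierarchy for model construction and evaluation."""


class AfeconError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AfeconError, ValueError):
    """A scalar input is outside its mathematical domain."""


class DegenerateParameterError(AfeconError, ValueError):
    """A parameter set over-fills a transition-matrix row (probabilities sum > 1)."""

    def __init__(self, state: str, total: float, message: str | None = None):
        self.state = state
        self.total = total
        super().__init__(
            message
            or f"per-cycle exit probabilities from state {state!r} sum to "
            f"{total:.6f} > 1; reduce rates or shorten the cycle"
        )


class SchemaError(AfeconError, ValueError):
    """Tabular input does not match the expected schema (states, years, columns)."""


class DistributionFitError(AfeconError, ValueError):
    """Method-of-moments fit is infeasible for the requested family."""


class CorruptedFixtureError(AfeconError, RuntimeError):
    """A packaged data file does not match its recorded checksum."""
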