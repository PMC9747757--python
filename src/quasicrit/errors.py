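"""Exception types shared across the package."""


class QuasicritError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(QuasicritError, ValueError):
    """An argument violates a documented precondition."""


class ConstructionFailureError(QuasicritError, RuntimeError):
    """Network construction could not satisfy its invariants."""


class DegenerateChannelError(QuasicritError, ValueError):
    """A recording channel is constant (zero variance) and cannot be z-scored."""

    def __init__(self, channel_id):
        self.channel_id = channel_id
        super().__init__(f"channel {channel_id!r} has zero standard deviation")


class FitFailureError(QuasicritError, RuntimeError):
    """A distribution or regression fit could not be performed."""


class UndefinedMetricError(QuasicritError, ValueError):
    """A statistic is undefined for the given input (e.g. zero mean rate)."""


class DegenerateCohortError(QuasicritError, ValueError):
    """A cohort-level computation is degenerate (e.g. non-positive projections)."""
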