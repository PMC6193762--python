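"""Exception types shared across the pipeline."""


class FlysinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FlysinError):
    """A data file does not conform to the expected CSV dialect."""


class OutOfBoundsError(FlysinError):
    """A centroid position lies outside the arena boundary."""


class UndefinedMetricError(FlysinError):
    """A statistic is undefined for the given input (e.g. zero variance,
    immobile fly, too few frames). Carries a human-readable reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class InfeasibleDesignError(FlysinError):
    """A dyad-pairing design cannot be constructed from the given parameters."""
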