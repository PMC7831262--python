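"""Exception types shared across the package."""


class PhenoscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenoscreenError, ValueError):
    """Invalid simulation or run configuration."""


class DegenerateControlError(PhenoscreenError, ValueError):
    """Control wells cannot support the requested statistic.

    Raised when the control mean is nonpositive (POC undefined) or the
    control SD is zero (a 3-SD threshold is meaningless); the caller is
    directed to the plate QC report.
    """


class InsufficientReplicatesError(PhenoscreenError, ValueError):
    """Fewer replicates than the statistic requires (e.g. n < 2 for an SD)."""


class InputConsistencyError(PhenoscreenError, ValueError):
    """Inputs contradict each other (e.g. more class hits than class members)."""
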