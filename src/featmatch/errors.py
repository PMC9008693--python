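"""Exception types shared across the package."""


class FeatmatchError(Exception):
    """Base class for all featmatch errors."""


class ConfigError(FeatmatchError, ValueError):
    """A configuration problem: missing column, inconsistent flags, bad threshold."""


class ValidationError(FeatmatchError, ValueError):
    """Input data violates an invariant (duplicate ids, infeasible parameters...)."""


class MissingDataError(FeatmatchError, ValueError):
    """An operation requires optional data (FI, npeaks, sample matrices) that is absent."""
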