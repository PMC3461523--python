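"""Package-specific error types."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all zeros)."""


class NoOverlapError(ValueError):
    """Recordings share no common time segment."""


class RankDeficiencyError(ValueError):
    """A covariance matrix is rank deficient and regularization is disabled."""


class ConfigError(ValueError):
    """An analysis configuration value is malformed; names the offending key."""
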