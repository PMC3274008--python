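"""Shared exception types."""


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented constraints.

    The message always names the offending field.
    """


class CoverageError(RuntimeError):
    """Raised when the fuzzy rule base produces zero activation for every
    output class (impossible under a valid membership configuration)."""
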