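"""Structured exception hierarchy."""


class MHNetError(Exception):
    """Base class for all package errors."""


class DataValidationError(MHNetError):
    """Malformed or inconsistent input data (non-finite values, shape
    mismatches, duplicate identifiers...)."""


class DegenerateInputError(MHNetError):
    """Numerically degenerate input, e.g. an all-constant signal matrix."""


class ConfigError(MHNetError):
    """Invalid configuration value."""


class NoKneeError(MHNetError):
    """Retained-edge curve has no detectable knee; a cutoff must be supplied
    explicitly."""
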