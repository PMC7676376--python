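"""Exception hierarchy shared across the package."""


class MegexError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MegexError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(MegexError):
    """Malformed input file (bad cell, mismatched samples, short GMT line...)."""


class InsufficientStudiesError(MegexError):
    """A combining step received fewer studies than it requires."""


class LfcUndefinedError(MegexError):
    """The log fold change is undefined (non-positive control mean)."""


class DegenerateDesignError(MegexError):
    """A regression design matrix is rank deficient; names the factor."""
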