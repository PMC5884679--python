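"""Exception hierarchy.

All data/parameter problems raise ValueError subclasses so callers can
catch broadly; the distinct classes let the CLI map them to exit codes.
"""


class PrsvarError(ValueError):
    """Base class for all prsvar input/parameter errors."""


class ParameterError(PrsvarError):
    """A simulation or analysis parameter is outside its valid domain."""


class InsufficientDataError(PrsvarError):
    """Too few observations to compute the requested statistic."""


class DomainError(PrsvarError):
    """Data violate a mathematical precondition (e.g. nonpositive mean)."""


class PairingError(PrsvarError):
    """Paired channels have mismatched lengths."""


class SchemaError(PrsvarError):
    """A table is missing required columns or has malformed values."""


class ConfigError(PrsvarError):
    """Pipeline configuration is invalid."""


class DependencyError(PrsvarError):
    """A pipeline stage was requested without the stage it depends on."""
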