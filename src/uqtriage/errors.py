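"""Exception types shared across the package."""


class UQTriageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(UQTriageError, ValueError):
    """Invalid configuration, e.g. a cohort spec field out of range or an
    unknown UQ metric name. The message names the offending field."""


class SchemaError(UQTriageError, ValueError):
    """A cohort file violates the on-disk schema. The message names the
    missing column or the (1-based) data row that fails validation."""


class DomainError(UQTriageError, ValueError):
    """Inputs outside an operation's mathematical domain, e.g. a single-class
    truth vector for an ROC statistic, or an empty score list."""
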