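"""Exception hierarchy used across the pipeline."""


class TumorhetError(Exception):
    """Base class for all package errors."""


class ConfigError(TumorhetError):
    """Invalid or missing configuration (CLI exit code 2)."""


class SchemaError(TumorhetError):
    """Input file violates the documented schema (CLI exit code 3)."""


class UndefinedFitError(TumorhetError):
    """A signature fit was requested for an empty spectrum."""


class InsufficientDataError(TumorhetError):
    """A group comparison was requested with fewer than two patients per group."""
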