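"""Exception hierarchy shared across the pipeline."""


class DeclinerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DeclinerError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(DeclinerError):
    """Variable schema and data disagree (unknown level, unmatched name, ...)."""


class DomainError(DeclinerError, ValueError):
    """An input outside the mathematical domain of an operation."""


class InsufficientDataError(DomainError):
    """Too few observations to carry out a fit."""


class DegenerateFeatureError(DeclinerError):
    """A feature with no usable variation (constant or empty observed set)."""


class CannotImputeError(DeclinerError):
    """Imputation impossible: a metabolite with zero detected values."""
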