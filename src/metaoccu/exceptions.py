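"""Exception hierarchy.

Everything derives from :class:`MetaoccuError` (itself a ``ValueError``) so
callers can catch package errors broadly or by kind.
"""


class MetaoccuError(ValueError):
    """Base class for all metaoccu errors."""


class AlignmentError(MetaoccuError):
    """Detection histories and covariates do not describe the same patches."""


class ParseError(MetaoccuError):
    """A cell in an input table could not be interpreted."""


class SpecError(MetaoccuError):
    """A model specification is invalid (unknown covariate, forbidden term)."""


class DomainError(MetaoccuError):
    """A numeric argument lies outside its mathematical domain."""


class UndefinedValueError(MetaoccuError):
    """A summary is undefined for the given data (e.g. single-class input)."""


class ConfigError(MetaoccuError):
    """A run configuration is malformed."""
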