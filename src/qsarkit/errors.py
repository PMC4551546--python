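"""Exception hierarchy.

All qsarkit errors derive from :class:`QsarkitError` so callers can catch the
whole family; the subclasses distinguish bad user configuration from bad data.
"""


class QsarkitError(Exception):
    """Base class for all qsarkit errors."""


class ConfigurationError(QsarkitError):
    """An option, column name or registry key the user supplied is invalid."""


class ParseError(QsarkitError):
    """A structure string could not be parsed."""


class DataValidationError(QsarkitError):
    """Input data violates a contract (shape, alphabet, missing column...)."""


class DomainError(QsarkitError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class DegenerateResponseError(QsarkitError):
    """The response has zero variance where a variance-normalised metric is asked for."""
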