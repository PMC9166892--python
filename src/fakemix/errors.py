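"""Exception hierarchy.

All package-specific failures derive from :class:`FakemixError` so callers
(and the CLI) can distinguish user/configuration problems from numerical
failures.
"""


class FakemixError(Exception):
    """Base class for all fakemix errors."""


class InvalidDesignError(FakemixError):
    """The questionnaire design is structurally invalid (e.g. block size < 2)."""


class ConfigurationError(FakemixError):
    """A configuration value is inconsistent (bad trait index, non-PD matrix, ...)."""


class DataError(FakemixError):
    """Observed data violate the model contract (e.g. response index out of 1..R)."""


class DomainError(FakemixError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class NumericalError(FakemixError):
    """A numerical routine failed to reach its accuracy target."""


class ParseError(DataError):
    """A text token could not be parsed (carries row/column context when known)."""
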