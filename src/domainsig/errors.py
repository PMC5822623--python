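"""Exception hierarchy for domainsig."""


class DomainsigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DomainsigError):
    """Invalid simulation or pipeline configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class InputError(DomainsigError):
    """Malformed or inconsistent input data."""


class UndefinedStatisticError(DomainsigError):
    """A statistic is undefined for the given input (e.g. constant vector)."""


class InsufficientDataError(DomainsigError):
    """Not enough samples/genes/pairs to carry out the requested operation."""
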