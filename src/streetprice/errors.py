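"""Exception hierarchy for the street-price pipeline."""


class StreetPriceError(Exception):
    """Base class for all package errors."""


class DomainError(StreetPriceError, ValueError):
    """An input violates a mathematical or schema precondition."""


class ConfigurationError(StreetPriceError, ValueError):
    """A config object or CLI option is invalid."""


class ExchangeRateError(StreetPriceError, LookupError):
    """No exchange rate is available for a requested date."""


class UnknownDrugError(StreetPriceError, KeyError):
    """A drug name is absent from the registry or conversion table."""
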