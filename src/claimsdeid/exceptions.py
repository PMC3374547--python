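"""Exception types raised across the package."""


class ClaimsDeidError(Exception):
    """Base class for all package errors."""


class SchemaError(ClaimsDeidError):
    """An input table is missing a required column or has an unusable layout."""


class IntegrityError(ClaimsDeidError):
    """Referential integrity between the patients and claims tables is broken."""


class ConfigurationError(ClaimsDeidError):
    """A configuration value is missing, malformed, or forbidden."""


class DomainError(ClaimsDeidError):
    """A value falls outside the domain an operation is defined on."""
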