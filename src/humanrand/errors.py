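"""Exception types shared across the package."""


class HumanrandError(Exception):
    """Base class for package errors."""


class ConfigurationError(HumanrandError):
    """A resource or configuration value is missing or unusable."""


class ValidationError(HumanrandError):
    """Input data violate a schema or an invariant."""


class DomainError(HumanrandError, ValueError):
    """An argument is outside the mathematical domain of an operation."""
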