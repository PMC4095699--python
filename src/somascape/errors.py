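"""Exception hierarchy shared across the package."""


class SomascapeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SomascapeError):
    """A run configuration or generator specification is invalid."""


class ValidationError(SomascapeError):
    """Input data violate a structural invariant (overlap, ordering, types)."""
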