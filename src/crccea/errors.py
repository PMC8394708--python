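"""Exception hierarchy shared across the analysis stages."""


class CRCCEAError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CRCCEAError, ValueError):
    """Raised when an operation receives data violating its contract."""


class ConfigurationError(CRCCEAError, ValueError):
    """Raised for bad run configuration (unknown currency pair, layout, ...)."""


class IntegrityError(CRCCEAError, RuntimeError):
    """Raised when packaged reference data fails its checksum."""
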