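"""Exception hierarchy shared across the pipeline."""


class MethcordError(Exception):
    """Base class for all package errors."""


class FormatError(MethcordError):
    """A file does not conform to its expected schema."""


class PairingError(MethcordError):
    """The sample sheet violates the matched-pair design."""


class ConfigError(MethcordError):
    """An invalid parameter or simulation configuration."""


class DomainError(MethcordError):
    """A numeric value is outside its valid domain (e.g. negative intensity)."""
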