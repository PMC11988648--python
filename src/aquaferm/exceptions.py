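"""Package-specific error types."""


class AquafermError(ValueError):
    """Base class for all aquaferm errors."""


class SchemaError(AquafermError):
    """A table does not satisfy the expected spectra/reference schema."""


class DegenerateSpectrumError(AquafermError):
    """An operation hit a spectrum it cannot transform (e.g. constant row in SNV)."""


class ConfigError(AquafermError):
    """A run configuration references something that does not exist."""
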