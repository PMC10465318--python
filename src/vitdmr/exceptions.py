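"""Exception types shared across the package."""


class VitdmrError(Exception):
    """Base class for package-specific errors."""


class ConfigError(VitdmrError, ValueError):
    """Invalid generator or analysis configuration."""


class SchemaError(VitdmrError, ValueError):
    """Cohort table violates the documented schema."""


class WeakInstrumentError(VitdmrError, RuntimeError):
    """Instrument too weak (or degenerate) to divide by safely."""


class SeparationError(VitdmrError, RuntimeError):
    """Logistic fit failed due to (quasi-)complete separation."""


class OneClassOutcomeError(VitdmrError, ValueError):
    """Outcome has a single class; odds ratios are undefined."""
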