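"""Exception hierarchy shared across the package."""


class AuditError(Exception):
    """Base class for all package-specific errors."""


class InputError(AuditError):
    """Unreadable or empty input file."""


class SchemaError(AuditError):
    """Input file header does not match the expected column schema."""


class ValidationError(AuditError):
    """A record violates a data-model invariant."""


class UnknownCylinderError(AuditError, LookupError):
    """A cylinder size code is not present in the registry."""


class ConfigurationError(AuditError):
    """Invalid configuration or generator parameters."""


class CalibrationError(ConfigurationError):
    """Calibration target unreachable within the admissible parameter range."""
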