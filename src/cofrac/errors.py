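"""Exception hierarchy shared across the pipeline."""


class CofracError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CofracError):
    """Invalid simulation or pipeline configuration."""


class FormatError(CofracError):
    """Malformed input file (bad header, duplicate ids, negative counts...)."""


class UsageError(CofracError):
    """Operation called with arguments that make it undefined."""


class CalibrationError(CofracError):
    """Calibration cannot be fitted (too few distinct standards)."""


class UndefinedMassError(CofracError):
    """Apparent mass is undefined (all-zero elution profile)."""
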