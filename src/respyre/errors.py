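"""Exception hierarchy for the respyre pipeline."""


class RespyreError(Exception):
    """Base class for all respyre errors."""


class ConfigError(RespyreError):
    """A configuration value is invalid or inconsistent."""


class DataError(RespyreError):
    """Input data violate a precondition (too short, all-missing, flat...)."""


class FormatError(RespyreError):
    """A file could be read but its layout is not the expected one."""


class CalibrationError(RespyreError):
    """Scaling calibration is impossible (e.g. no reference data)."""
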