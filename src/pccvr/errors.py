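"""Exception types shared across the package."""


class PccvrError(Exception):
    """Base class for package errors."""


class ConfigError(PccvrError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(PccvrError, ValueError):
    """Missing, corrupt or inconsistent study data."""


class UndefinedCVRError(PccvrError, ZeroDivisionError):
    """CVR is undefined because the stimulus delta is zero."""
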