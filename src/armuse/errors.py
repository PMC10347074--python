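"""Exception types shared across the pipeline stages."""


class ArmUseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ArmUseError):
    """Invalid session or pipeline configuration (negative durations, bad rates...)."""


class ParseError(ArmUseError):
    """Malformed interchange CSV (missing column, non-numeric cell...)."""


class SyncError(ArmUseError):
    """Synchronization failure: missing calibration bursts, lag at search boundary,
    flat signal, or an empty interval between the two calibration events."""


class SignatureError(ArmUseError):
    """Feature-order signature of a model does not match the supplied features."""
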