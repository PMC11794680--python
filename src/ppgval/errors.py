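"""Exception hierarchy for the validation pipeline."""


class PpgvalError(Exception):
    """Base class for all pipeline errors."""


class IngestError(PpgvalError):
    """Raised when an input file cannot be parsed into the data model."""


class SyncError(PpgvalError):
    """Raised when two streams cannot be aligned (e.g. insufficient overlap)."""


class ConfigError(PpgvalError):
    """Raised on invalid configuration (overlapping windows, missing calibration...)."""


class PreprocessError(PpgvalError):
    """Raised when artifact correction cannot proceed (nothing to anchor
    interpolation, or the adaptive threshold cap is reached with flags left)."""
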