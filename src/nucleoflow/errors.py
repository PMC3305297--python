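"""Exception hierarchy for nucleoflow."""


class NucleoflowError(Exception):
    """Base class for all nucleoflow errors."""


class ConfigError(NucleoflowError):
    """Invalid generator/gating/run configuration."""


class DataError(NucleoflowError):
    """Malformed, empty, or degenerate input data."""


class CalibrationError(NucleoflowError):
    """Counting-bead calibration cannot be performed (e.g. no bead events)."""


class GatingError(NucleoflowError):
    """Event gating failed (e.g. DNA line mode not identifiable)."""
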