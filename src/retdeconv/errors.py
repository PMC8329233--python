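"""Exception types shared across the pipeline."""


class RetdeconvError(Exception):
    """Base class for package errors."""


class ConfigError(RetdeconvError, ValueError):
    """A configuration value is missing, out of range, or unknown."""


class DimensionError(RetdeconvError, ValueError):
    """Inputs disagree in shape or gene/sample sets."""


class AnalysisError(RetdeconvError, RuntimeError):
    """A computation cannot proceed on the given data (degenerate input)."""
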