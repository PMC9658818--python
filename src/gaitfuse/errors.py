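"""Structured exceptions shared across the pipeline."""


class GaitFuseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GaitFuseError, ValueError):
    """A configuration value is invalid or inconsistent."""


class DegenerateSignalError(GaitFuseError, ValueError):
    """A signal is degenerate for the requested feature (e.g. zero variance)."""


class TotalConflictError(GaitFuseError, ArithmeticError):
    """Dempster combination met total conflict (K = 1); nothing can be renormalized."""
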