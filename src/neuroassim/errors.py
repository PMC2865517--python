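"""Exception types shared across the package."""


class NeuroassimError(Exception):
    """Base class for package errors."""


class ConfigError(NeuroassimError, ValueError):
    """Invalid configuration: unknown key, bad unit, out-of-range parameter."""


class DomainError(NeuroassimError, ValueError):
    """Model state outside its physical domain (e.g. non-positive concentration)."""


class DivergenceError(NeuroassimError, RuntimeError):
    """Numerical integration left the valid operating range."""

    def __init__(self, message: str, last_valid_time_ms: float | None = None):
        super().__init__(message)
        self.last_valid_time_ms = last_valid_time_ms


class FilterDivergenceError(NeuroassimError, RuntimeError):
    """A sigma point or the filter state diverged mid-run."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class NoSeizureRegimeError(NeuroassimError, RuntimeError):
    """A fixture preset expected a seizure-like episode but none was detected."""


class TraceParseError(NeuroassimError, ValueError):
    """Malformed delimited trace file."""
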