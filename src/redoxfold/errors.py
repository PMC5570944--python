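"""Exception hierarchy for redoxfold."""


class RedoxfoldError(Exception):
    """Base class for all package errors."""


class GeometryError(RedoxfoldError, ValueError):
    """Invalid geometry: non-positive distances, overlapping particles."""


class TopologyError(RedoxfoldError, ValueError):
    """Inconsistent topology or out-of-range particle references."""


class ConfigError(RedoxfoldError, ValueError):
    """Invalid or unknown configuration keys / values."""


class ParseError(RedoxfoldError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ReplayError(RedoxfoldError, RuntimeError):
    """Fatal reproducibility failure: a replayed segment diverged."""


class RampFailureError(RedoxfoldError, RuntimeError):
    """Restraint ramp diverged from its target over consecutive windows."""


class IntegrationBlowupError(RedoxfoldError, RuntimeError):
    """Non-finite coordinates produced by the integrator."""


class GenerationError(RedoxfoldError, RuntimeError):
    """Synthetic-chain placement failed after bounded retries."""
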