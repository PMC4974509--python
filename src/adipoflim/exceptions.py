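"""Exception hierarchy for adipoflim.

All package-specific failures derive from :class:`AdipoFlimError` so callers
can catch one base class at pipeline boundaries.
"""


class AdipoFlimError(Exception):
    """Base class for all adipoflim errors."""


class ValidationError(AdipoFlimError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(AdipoFlimError, ValueError):
    """A file does not conform to the documented container layout."""


class ConfigError(AdipoFlimError, ValueError):
    """A run configuration is malformed or contains unknown keys."""


class CalibrationError(AdipoFlimError, ValueError):
    """Reference calibration is degenerate (e.g. zero-modulus phasor)."""


class PackingError(AdipoFlimError, RuntimeError):
    """Phantom droplet packing could not reach its target within the
    attempt budget."""


class StageError(AdipoFlimError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
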