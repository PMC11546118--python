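"""Exception hierarchy shared across the package."""


class FFProteoError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FFProteoError, ValueError):
    """Invalid configuration; ``field`` names the offending entry."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ParseError(FFProteoError, ValueError):
    """Malformed input file; ``row`` is the 1-based data-row number when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class PipelineError(FFProteoError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class ReproducibilityError(FFProteoError, RuntimeError):
    """A replayed run did not reproduce the recorded artifact checksums."""
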