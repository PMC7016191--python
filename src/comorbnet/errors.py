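"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class ComorbnetError(Exception):
    """Base class for all package errors."""


class InputError(ComorbnetError):
    """Unreadable or malformed input tables."""


class ConfigError(ComorbnetError):
    """Invalid simulation or pipeline configuration."""


class ConvergenceError(ComorbnetError):
    """Iterative computation failed to converge within its budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FixtureIntegrityError(ComorbnetError):
    """Packaged fixture failed its checksum or shape check."""
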