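"""Exception hierarchy.

Everything raised on bad user input derives from :class:`GameNetError`
so callers (and the CLI) can catch one type and exit cleanly.
"""


class GameNetError(ValueError):
    """Base class for all domain errors raised by gamenet."""


class ConfigError(GameNetError):
    """Invalid game configuration."""


class RosterError(GameNetError):
    """Invalid actor roster, or log actors missing from the roster."""


class LogFormatError(GameNetError):
    """Malformed interaction-log file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SilentNetworkError(GameNetError):
    """Raised when diversity is requested on a network with no interactions.

    Evenness of an empty exchange distribution is undefined, so the
    caller must decide how to record it (the longitudinal pipeline marks
    such windows as missing).
    """
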