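"""Exception hierarchy.

Each error carries a short machine-readable ``code`` so the CLI can map
failures onto distinct exit codes and messages.
"""

from __future__ import annotations


class RisizeError(Exception):
    """Base class for all package errors."""

    code: str = "error"

    def __init__(self, message: str, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class InputError(RisizeError):
    """Invalid user input: bad data, missing columns, malformed files."""

    code = "invalid-input"


class ConfigError(RisizeError):
    """Invalid configuration value (unknown summary name, bad grid bounds...)."""

    code = "invalid-config"


class DomainError(RisizeError):
    """A value lies outside the mathematical domain of a transform."""

    code = "domain"


class DegenerateDataError(RisizeError):
    """Resampling produced persistently degenerate replicates."""

    code = "degenerate"
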