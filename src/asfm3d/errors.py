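"""Exception hierarchy shared across the pipeline.

Each class carries the process exit code the command-line layer maps it to,
so library errors translate deterministically into shell semantics.
"""

from __future__ import annotations


class AsfmError(Exception):
    """Base class for all pipeline errors."""

    exit_code: int = 1

    def __init__(self, message: str, *, stage: str | None = None):
        self.stage = stage
        super().__init__(message if stage is None else f"[{stage}] {message}")


class InputFormatError(AsfmError):
    """Malformed or unreadable input/output file (exit code 2)."""

    exit_code = 2


class ValidationError(AsfmError):
    """Input violates a documented contract (exit code 3)."""

    exit_code = 3


class DegenerateGeometryError(AsfmError):
    """Point configuration admits no well-defined geometric answer (exit code 4)."""

    exit_code = 4
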