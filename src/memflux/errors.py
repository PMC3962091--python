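"""Exception hierarchy.

All package errors derive from :class:`MemfluxError` so callers can catch
one base class; the CLI maps validation errors and computation errors to
distinct exit codes.
"""


class MemfluxError(Exception):
    """Base class for all memflux errors."""


class UnitError(MemfluxError):
    """Unknown or unsupported physical unit."""


class StructureParseError(MemfluxError):
    """A structure file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SelectionError(MemfluxError):
    """An atom selection left no atoms, or referenced absent chains/models."""


class MoleculeExcludedError(MemfluxError):
    """The solute is too large to enter the pore (steric exclusion)."""


class ConfigError(MemfluxError):
    """Invalid or incomplete run/membrane configuration; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")
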