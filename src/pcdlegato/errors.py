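"""Typed error hierarchy.

Every failure mode the engine can report deliberately — a malformed menu
file, an unresolvable placeholder, a missing program output — raises a
subclass of :class:`PCDError`, never a bare built-in exception, so callers
(and the CLI) can distinguish user errors from bugs.
"""

from __future__ import annotations


class PCDError(Exception):
    """Base class for all engine errors."""


class PCDParseError(PCDError):
    """A ``.blmenu`` file is syntactically or semantically invalid.

    Carries the source path (when known) and the 1-based line number of
    the offending line.
    """

    def __init__(self, message: str, *, line: int | None = None,
                 source: str | None = None):
        self.line = line
        self.source = source
        where = ""
        if source:
            where += f"{source}:"
        if line is not None:
            where += f"line {line}: "
        elif source:
            where += " "
        super().__init__(where + message)


class UnsetVariableError(PCDError):
    """An ``$NAME`` environment reference names a variable that is not set."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"environment variable is not set: {name}")


class PlaceholderError(PCDError):
    """A ``%NAME%`` token survived substitution with no var to resolve it."""

    def __init__(self, names: list[str]):
        self.names = list(names)
        super().__init__("undefined placeholder(s): " + ", ".join(self.names))


class SubstitutionCycleError(PCDError):
    """Chooser fragments reference each other in a cycle."""


class ParameterError(PCDError):
    """A user-supplied parameter value is unknown, malformed or out of range."""


class CanvasError(PCDError):
    """Canvas content or format violation (bad FASTA, tab in a TSV cell...)."""


class OutputMissingError(PCDError):
    """The wrapped program exited 0 but an expected output file is absent."""

    def __init__(self, path, stderr: str = ""):
        self.path = path
        self.stderr = stderr
        excerpt = (stderr or "").strip().splitlines()
        tail = ("; stderr: " + excerpt[-1]) if excerpt else ""
        super().__init__(f"expected output file not produced: {path}{tail}")


class AppError(PCDError):
    """An application ``.properties`` definition is unusable."""


class MenuTreeError(PCDError):
    """No usable menu root, or a named menu item does not exist."""
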