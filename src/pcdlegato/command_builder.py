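"""Build executable command plans from a menu plus user parameter values.

The engine's core move: take the ``shell`` template of a menu, substitute
environment variables (``$NAME``), then substitute ``%NAME%`` placeholders
to a fixed point — a chooser's value is the command *fragment* attached to
the chosen label, and that fragment may itself contain further
placeholders (the classic case: an output chooser whose fragment contains
``%out1%``). Temp-file vars allocate fresh unique paths under a private
working directory, and each out-direction temp file carries a routing
directive saying what happens to its content after the run: merged into
the current canvas, replacing it entirely (``overwrite true``), or loaded
into a new application instance (fragment marked ``%NEWINSTANCE%``).
"""

from __future__ import annotations

import os
import re
import secrets
import shlex
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import (ParameterError, PlaceholderError, SubstitutionCycleError,
                     UnsetVariableError)
from .pcd_parser import (MenuSpec, VarSpec, RESERVED_PLACEHOLDERS,
                         PLACEHOLDER_RE, iter_placeholders)

MERGE_CURRENT = "merge_current"
REPLACE_CURRENT = "replace_current"
NEW_INSTANCE = "new_instance"

_ENV_RE = re.compile(r"\$(?:\{(\w+)\}|(\w+))")
_SENTINEL = "\x00"


def expand_env(text: str, env: dict[str, str]) -> str:
    """Expand ``$NAME`` and ``${NAME}`` from ``env``; ``%NAME%`` untouched.

    Raises :class:`UnsetVariableError` naming the first unset variable.
    """
    def sub(m: re.Match) -> str:
        name = m.group(1) or m.group(2)
        if name not in env:
            raise UnsetVariableError(name)
        return env[name]
    return _ENV_RE.sub(sub, text)


def resolve_widget_bounds(var: VarSpec, env: dict[str, str]) -> VarSpec:
    """Strictly resolve a numeric var's min/default/max from the environment.

    Menus routinely defer widget bounds to the launching wrapper script —
    e.g. a thread-count slider whose maximum is the machine's core count,
    passed in as an environment variable — so bounds may arrive here as
    ``$NAME`` references rather than numbers.
    """
    if not var.is_numeric:
        raise ParameterError(f"var {var.name!r} is not numeric")

    def resolve(value: object, what: str):
        if isinstance(value, (int, float)):
            return value
        text = expand_env(str(value), env)
        try:
            f = float(text)
        except ValueError:
            raise ParameterError(
                f"var {var.name!r}: {what} is not numeric after expansion: "
                f"{text!r}") from None
        return int(f) if f == int(f) else f

    vmin = resolve(var.min, "min")
    vmax = resolve(var.max, "max")
    default = resolve(var.default, "default")
    if not (vmin <= default <= vmax):
        raise ParameterError(
            f"var {var.name!r}: min {vmin} <= default {default} <= max {vmax} "
            "fails")
    return replace(var, min=vmin, max=vmax, default=default)


class TempAllocator:
    """Allocates unique temp-file paths for one command plan.

    Paths are ``<workdir>/<varname>-<8 hex>``. With no arguments the
    workdir is a fresh private directory and tokens are unpredictable;
    pinning ``workdir`` and ``seed`` makes allocation fully reproducible.
    """

    def __init__(self, workdir: str | os.PathLike | None = None,
                 seed: int | None = None):
        self.workdir = Path(workdir) if workdir is not None else Path(
            tempfile.mkdtemp(prefix="pcdlegato-"))
        if seed is None:
            self._token = lambda: secrets.token_hex(4)
        else:
            import random
            rng = random.Random(seed)
            self._token = lambda: f"{rng.getrandbits(32):08x}"
        self._seen: set[Path] = set()

    def allocate(self, var_name: str) -> Path:
        while True:
            path = self.workdir / f"{var_name}-{self._token()}"
            if path not in self._seen:
                self._seen.add(path)
                return path


@dataclass(frozen=True)
class CommandPlan:
    """A fully substituted command plus its temp-file contract."""

    command: str
    temp_in: dict[str, tuple[Path, str]] = field(default_factory=dict)
    temp_out: dict[str, tuple[Path, str]] = field(default_factory=dict)
    workdir: Path = Path(".")

    def to_debug_dict(self) -> dict:
        """JSON-serializable dump for ``--dry-run``."""
        return {
            "command": self.command,
            "workdir": str(self.workdir),
            "temp_in": {k: {"path": str(p), "format": f}
                        for k, (p, f) in self.temp_in.items()},
            "temp_out": {k: {"path": str(p), "routing": r}
                         for k, (p, r) in self.temp_out.items()},
        }


def _render_value(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return str(int(value)) if value == int(value) else repr(value)
    text = str(value)
    if any(c.isspace() for c in text):
        return shlex.quote(text)
    return text


def validate_values(spec: MenuSpec, values: dict[str, object],
                    env: dict[str, str]) -> dict[str, object]:
    """Merge user values over defaults and validate against the menu.

    Keys match var names case-insensitively. Numeric values must lie in
    the var's (env-resolved) bounds; chooser values must name one of the
    declared choice labels. Returns a complete name -> value mapping for
    every non-tempfile var.
    """
    canon = {name.lower(): name for name in spec.vars}
    merged: dict[str, object] = {}
    for var in spec.vars.values():
        if var.kind != "tempfile":
            merged[var.name] = var.default
    for key, value in values.items():
        if key.lower() not in canon:
            raise ParameterError(f"unknown parameter {key!r}")
        name = canon[key.lower()]
        var = spec.vars[name]
        if var.kind == "tempfile":
            raise ParameterError(f"{name!r} is a temp-file binding, not a "
                                 "settable parameter")
        merged[name] = value

    for name, value in merged.items():
        var = spec.vars[name]
        if var.is_numeric:
            resolved = resolve_widget_bounds(var, env)
            try:
                num = float(value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ParameterError(
                    f"var {name!r}: value {value!r} is not numeric") from None
            if not (resolved.min <= num <= resolved.max):  # type: ignore
                raise ParameterError(
                    f"var {name!r}: value {num:g} outside "
                    f"[{resolved.min}, {resolved.max}]")
            merged[name] = int(num) if num == int(num) else num
        elif var.is_chooser:
            if value not in var.choices:
                raise ParameterError(
                    f"var {name!r}: {value!r} is not one of "
                    f"{list(var.choices)}")
    return merged


def build_command(spec: MenuSpec, values: dict[str, object] | None = None,
                  env: dict[str, str] | None = None,
                  temp_allocator: TempAllocator | None = None,
                  panel_index: int = 0) -> CommandPlan:
    """Substitute a menu's command template to a fixed point.

    Substitution runs in passes: each pass replaces every resolvable
    ``%NAME%`` token at once (chooser tokens by their chosen fragment,
    scalar vars by their rendered value, temp-file vars by a freshly
    allocated path, ``%NEWINSTANCE%`` by nothing). Fragments introduce new
    tokens, so passes repeat until the text is stable; more passes than
    declared vars plus one means the fragments reference each other in a
    cycle, which is reported rather than looped on.

    Temp paths are allocated lazily, only for vars whose placeholder
    actually appears, in first-appearance order — so a template with no
    placeholders yields empty temp maps.

    Raises
    ------
    ParameterError, PlaceholderError, SubstitutionCycleError,
    UnsetVariableError
    """
    env = env or {}
    values = values or {}
    alloc = temp_allocator or TempAllocator()
    merged = validate_values(spec, values, env)
    canon = {name.lower(): name for name in spec.vars}

    # replacement text per placeholder, built lazily for tempfiles
    allocated: dict[str, Path] = {}

    def replacement(token: str) -> str | None:
        if token in RESERVED_PLACEHOLDERS:
            return ""
        name = canon.get(token.lower())
        if name is None:
            return None
        var = spec.vars[name]
        if var.kind == "tempfile":
            if name not in allocated:
                allocated[name] = alloc.allocate(name)
            return str(allocated[name])
        value = merged[name]
        if var.is_chooser:
            return expand_env(var.choices[str(value)], env)
        return _render_value(value)

    text = expand_env(spec.panels[panel_index].shell_template,
                      env).replace("%%", _SENTINEL)
    max_passes = len(spec.vars) + 1
    passes = 0
    while True:
        tokens = PLACEHOLDER_RE.findall(text)
        if not tokens:
            break
        if passes >= max_passes:
            raise SubstitutionCycleError(
                "placeholder substitution did not reach a fixed point "
                f"after {passes} passes; fragments likely form a cycle: "
                f"{sorted(set(tokens))}")

        def sub(m: re.Match) -> str:
            rep = replacement(m.group(1))
            if rep is None:
                return m.group(0)
            return rep.replace("%%", _SENTINEL)

        new_text = PLACEHOLDER_RE.sub(sub, text)
        if new_text == text:
            undefined = sorted({t for t in tokens if replacement(t) is None})
            if not undefined:  # a token replaced by itself
                raise SubstitutionCycleError(
                    f"fragment substitutes to itself: {sorted(set(tokens))}")
            raise PlaceholderError(undefined)
        text = new_text
        passes += 1

    command = text.replace(_SENTINEL, "%").strip()

    # routing: fragments carrying %NEWINSTANCE% direct their out-files to
    # a fresh application instance; otherwise the overwrite flag decides.
    new_instance_outs: set[str] = set()
    for name, value in merged.items():
        var = spec.vars[name]
        if not var.is_chooser:
            continue
        fragment = var.choices[str(value)]
        frag_tokens = set(iter_placeholders(fragment))
        if "NEWINSTANCE" in frag_tokens:
            for token in frag_tokens:
                ref = canon.get(token.lower())
                if ref and spec.vars[ref].direction == "out":
                    new_instance_outs.add(ref)

    temp_in: dict[str, tuple[Path, str]] = {}
    temp_out: dict[str, tuple[Path, str]] = {}
    for name, path in allocated.items():
        var = spec.vars[name]
        if var.direction == "in":
            temp_in[name] = (path, var.format)
        elif var.direction == "out":
            if name in new_instance_outs:
                routing = NEW_INSTANCE
            elif var.overwrite:
                routing = REPLACE_CURRENT
            else:
                routing = MERGE_CURRENT
            temp_out[name] = (path, routing)

    return CommandPlan(command=command, temp_in=temp_in, temp_out=temp_out,
                       workdir=alloc.workdir)


__all__ = [
    "CommandPlan", "TempAllocator", "build_command", "expand_env",
    "resolve_widget_bounds", "validate_values",
    "MERGE_CURRENT", "REPLACE_CURRENT", "NEW_INSTANCE",
]
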