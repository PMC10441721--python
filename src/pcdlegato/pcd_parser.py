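"""PCD menu parser and serializer.

PCD is a small indentation-sensitive language: one ``.blmenu`` file
describes one parameter menu for one wrapped command-line program — a
title, optional icon and tool-tip, a set of ``var`` declarations (the
user-settable parameters and temp-file bindings), and a ``panel`` whose
``shell`` line is the command template. Values are substituted into the
template wherever the var's name appears between ``%`` signs; any part of
a menu may reference environment variables as ``$NAME`` or ``${NAME}``.

The concrete grammar accepted here is documented in
``docs/pcd-grammar.md``; the shipped ``data/shuffle.blmenu`` is the
reference example. Indentation is significant (tabs count as 8 columns)
and must be consistent within a file, in the way Python requires.

Placeholders are matched to var names case-insensitively: a var declared
``window`` is addressed as ``%WINDOW%`` in the template. ``%%`` escapes a
literal percent sign. The single reserved placeholder ``%NEWINSTANCE%``
marks a chooser fragment as routing its output files into a new
application instance; it substitutes to nothing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .errors import PCDParseError

log = logging.getLogger(__name__)

#: var widget kinds
KINDS = ("text", "number", "slider", "chooser", "choice-list", "file", "tempfile")
NUMERIC_KINDS = ("number", "slider")
CHOOSER_KINDS = ("chooser", "choice-list")

#: placeholder names that are always resolvable without a var declaration
RESERVED_PLACEHOLDERS = frozenset({"NEWINSTANCE"})

PLACEHOLDER_RE = re.compile(r"%([A-Za-z0-9_]+)%")
_ENV_NUMERIC_RE = re.compile(r"^\$(?:\{(\w+)\}|(\w+))$")
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")

TAB_WIDTH = 8
INDENT = "    "  # canonical serializer indent


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class VarSpec:
    """One ``var`` declaration: a parameter or temp-file binding.

    ``min``/``max``/``default`` of numeric kinds may hold an unresolved
    ``$NAME`` reference (kept as text) when the variable was not set in
    the environment given at parse time; they are resolved strictly when
    a command is built.
    """

    name: str
    kind: str
    label: str = ""
    default: object = None          # str | int | float | None
    min: object = None              # int | float | "$REF" | None
    max: object = None
    choices: dict[str, str] = field(default_factory=dict)  # label -> fragment
    direction: str = "none"         # tempfile: in | out | none
    overwrite: bool = False         # tempfile out only
    format: str = "text"            # canvas export format for in-tempfiles

    @property
    def is_numeric(self) -> bool:
        return self.kind in NUMERIC_KINDS

    @property
    def is_chooser(self) -> bool:
        return self.kind in CHOOSER_KINDS


@dataclass(frozen=True)
class PanelSpec:
    """A panel: parameter layout (tabs) plus the command template."""

    tabs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    run_label: str = "Run"
    shell_template: str = ""


@dataclass(frozen=True)
class MenuSpec:
    """One parsed menu: what a single ``.blmenu`` file declares."""

    title: str
    icon: str = ""
    tip: str = ""
    vars: dict[str, VarSpec] = field(default_factory=dict)
    panels: tuple[PanelSpec, ...] = ()
    source: str = field(default="", compare=False)

    def var(self, name: str) -> VarSpec:
        """Look a var up by name, case-insensitively."""
        low = name.lower()
        for key, spec in self.vars.items():
            if key.lower() == low:
                return spec
        raise KeyError(name)


# ---------------------------------------------------------------------------
# lexing


@dataclass
class _Line:
    indent: int
    tokens: list[tuple[str, str]]  # (kind 'atom'|'str', text)
    lineno: int

    @property
    def keyword(self) -> str:
        kind, text = self.tokens[0]
        return text if kind == "atom" else ""


def _tokenize(content: str, lineno: int, source: str | None) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    i, n = 0, len(content)
    while i < n:
        c = content[i]
        if c in " \t":
            i += 1
            continue
        if c == '"':
            out = []
            i += 1
            while i < n and content[i] != '"':
                if content[i] == "\\" and i + 1 < n:
                    nxt = content[i + 1]
                    if nxt in '"\\':
                        out.append(nxt)
                        i += 2
                        continue
                    if nxt in "nrt":
                        out.append({"n": "\n", "r": "\r", "t": "\t"}[nxt])
                        i += 2
                        continue
                out.append(content[i])
                i += 1
            if i >= n:
                raise PCDParseError("unterminated string", line=lineno, source=source)
            i += 1
            tokens.append(("str", "".join(out)))
        else:
            j = i
            while j < n and content[j] not in ' \t"':
                j += 1
            tokens.append(("atom", content[i:j]))
            i = j
    return tokens


def _measure_indent(raw: str, lineno: int, source: str | None) -> tuple[int, str]:
    col = 0
    for i, ch in enumerate(raw):
        if ch == " ":
            col += 1
        elif ch == "\t":
            col += TAB_WIDTH - col % TAB_WIDTH
        else:
            return col, raw[i:]
    return col, ""


def _lex(text: str, source: str | None) -> list[_Line]:
    lines: list[_Line] = []
    # split on LF only (CRLF accepted); other control characters are data
    for lineno, raw in enumerate(text.split("\n"), start=1):
        raw = raw.rstrip("\r")
        col, content = _measure_indent(raw, lineno, source)
        if not content or content.startswith("#"):
            continue
        tokens = _tokenize(content, lineno, source)
        if not tokens:
            continue
        lines.append(_Line(col, tokens, lineno))
    return lines


# ---------------------------------------------------------------------------
# block structure


@dataclass
class _Node:
    line: _Line
    children: list["_Node"] = field(default_factory=list)


def _build_blocks(lines: list[_Line], source: str | None) -> list[_Node]:
    """Group lines into a tree by indentation, Python-style.

    Each deeper indent level must be strictly greater than its parent's,
    and a dedent must return to a previously seen level.
    """
    roots: list[_Node] = []
    stack: list[tuple[int, _Node]] = []  # (indent, node)
    for line in lines:
        node = _Node(line)
        while stack and line.indent <= stack[-1][0]:
            stack.pop()
        if not stack:
            if line.indent != 0:
                raise PCDParseError("unexpected indent", line=line.lineno,
                                    source=source)
            roots.append(node)
        else:
            parent_indent, parent = stack[-1]
            # all siblings under one parent must share an indent level
            if parent.children and parent.children[0].line.indent != line.indent:
                raise PCDParseError("inconsistent indentation", line=line.lineno,
                                    source=source)
            parent.children.append(node)
        stack.append((line.indent, node))
    return roots


# ---------------------------------------------------------------------------
# parsing proper


def _one_string_arg(node: _Node, source: str | None) -> str:
    toks = node.line.tokens[1:]
    if len(toks) != 1:
        raise PCDParseError(
            f"'{node.line.keyword}' takes exactly one value",
            line=node.line.lineno, source=source)
    return toks[0][1]


def _parse_scalar(text: str) -> object:
    """An attribute value: number if it looks like one, else text."""
    if _NUMBER_RE.match(text):
        f = float(text)
        return int(f) if f == int(f) and "." not in text and "e" not in text.lower() else f
    return text


def _expand_numeric(value: object, env: dict[str, str]):
    """Expand a ``$NAME`` numeric attribute from env if the name is set.

    Unset references are kept verbatim for later strict resolution (the
    slider-bounds mechanism: menus may defer bounds to wrapper-script
    environment variables).
    """
    if not isinstance(value, str):
        return value
    m = _ENV_NUMERIC_RE.match(value)
    if not m:
        return value
    name = m.group(1) or m.group(2)
    if name in env:
        return _parse_scalar(env[name])
    return value


def _require_number(value: object, what: str, var: str, lineno: int,
                    source: str | None):
    if isinstance(value, (int, float)):
        return value
    raise PCDParseError(
        f"var '{var}': {what} is not a number after expansion: {value!r}",
        line=lineno, source=source)


def _parse_var(node: _Node, env: dict[str, str], source: str | None) -> VarSpec:
    name = _one_string_arg(node, source)
    lineno = node.line.lineno
    attrs: dict[str, object] = {}
    choices: dict[str, str] = {}
    for child in node.children:
        kw = child.line.keyword
        if kw == "choices":
            for entry in child.children:
                toks = entry.line.tokens
                if len(toks) != 2:
                    raise PCDParseError(
                        "a choice line is: <label> <fragment>",
                        line=entry.line.lineno, source=source)
                label, fragment = toks[0][1], toks[1][1]
                if label in choices:
                    raise PCDParseError(f"duplicate choice label {label!r}",
                                        line=entry.line.lineno, source=source)
                choices[label] = fragment
        elif kw in ("type", "label", "default", "min", "max",
                    "direction", "overwrite", "format"):
            if child.children:
                raise PCDParseError(f"'{kw}' does not open a block",
                                    line=child.line.lineno, source=source)
            attrs[kw] = _one_string_arg(child, source)
        else:
            log.warning("%s:%d: unknown var attribute %r ignored",
                        source or "<string>", child.line.lineno, kw)

    kind = str(attrs.get("type", "text"))
    if kind not in KINDS:
        raise PCDParseError(f"var '{name}': unknown type {kind!r}",
                            line=lineno, source=source)

    default: object = attrs.get("default")
    vmin: object = attrs.get("min")
    vmax: object = attrs.get("max")
    if kind in NUMERIC_KINDS:
        missing = [k for k, v in (("min", vmin), ("default", default),
                                  ("max", vmax)) if v is None]
        if missing:
            raise PCDParseError(
                f"var '{name}': numeric kind requires {', '.join(missing)}",
                line=lineno, source=source)
        vmin = _expand_numeric(_parse_scalar(str(vmin)), env)
        vmax = _expand_numeric(_parse_scalar(str(vmax)), env)
        default = _expand_numeric(_parse_scalar(str(default)), env)
        resolved = [v for v in (vmin, default, vmax)
                    if isinstance(v, (int, float))]
        if len(resolved) == 3:
            if not (vmin <= default <= vmax):  # type: ignore[operator]
                raise PCDParseError(
                    f"var '{name}': bounds violated: "
                    f"min {vmin} <= default {default} <= max {vmax} fails",
                    line=lineno, source=source)
        else:
            for v in (vmin, default, vmax):
                if isinstance(v, str) and not _ENV_NUMERIC_RE.match(v):
                    _require_number(v, "numeric attribute", name, lineno, source)

    if kind in CHOOSER_KINDS:
        if not choices:
            raise PCDParseError(f"var '{name}': chooser requires choices",
                                line=lineno, source=source)
        if default is None:
            default = next(iter(choices))
        if default not in choices:
            raise PCDParseError(
                f"var '{name}': default {default!r} is not a choice label",
                line=lineno, source=source)
    elif choices:
        raise PCDParseError(
            f"var '{name}': 'choices' only applies to chooser kinds",
            line=lineno, source=source)

    direction = str(attrs.get("direction", "none"))
    if kind == "tempfile":
        if direction not in ("in", "out", "none"):
            raise PCDParseError(
                f"var '{name}': direction must be in, out or none",
                line=lineno, source=source)
    elif "direction" in attrs:
        raise PCDParseError(f"var '{name}': 'direction' only applies to tempfile",
                            line=lineno, source=source)

    overwrite_text = str(attrs.get("overwrite", "false")).lower()
    if overwrite_text not in ("true", "false"):
        raise PCDParseError(f"var '{name}': overwrite must be true or false",
                            line=lineno, source=source)
    overwrite = overwrite_text == "true"
    if overwrite and not (kind == "tempfile" and direction == "out"):
        raise PCDParseError(
            f"var '{name}': overwrite applies only to out-direction tempfiles",
            line=lineno, source=source)

    return VarSpec(
        name=name, kind=kind, label=str(attrs.get("label", "")),
        default=default, min=vmin, max=vmax, choices=choices,
        direction=direction if kind == "tempfile" else "none",
        overwrite=overwrite, format=str(attrs.get("format", "text")),
    )


def _parse_panel(node: _Node, var_names: dict[str, str],
                 source: str | None) -> PanelSpec:
    tabs: dict[str, list[str]] = {}
    run_label = "Run"
    shell = ""

    def add_tab_entry(tab: str, entry_node: _Node):
        toks = entry_node.line.tokens
        if len(toks) != 1:
            raise PCDParseError("a tab entry is a single var name",
                                line=entry_node.line.lineno, source=source)
        ref = toks[0][1]
        if ref.lower() not in var_names:
            raise PCDParseError(f"panel references unknown var {ref!r}",
                                line=entry_node.line.lineno, source=source)
        tabs.setdefault(tab, []).append(var_names[ref.lower()])

    for child in node.children:
        kw = child.line.keyword
        if kw == "shell":
            shell = _one_string_arg(child, source)
        elif kw == "runlabel":
            run_label = _one_string_arg(child, source)
        elif kw == "tab":
            tab_name = _one_string_arg(child, source)
            if tab_name in tabs:
                raise PCDParseError(f"duplicate tab {tab_name!r}",
                                    line=child.line.lineno, source=source)
            tabs[tab_name] = []
            for entry in child.children:
                add_tab_entry(tab_name, entry)
        elif child.line.tokens[0][0] == "str" or kw.lower() in var_names:
            add_tab_entry("", child)
        else:
            log.warning("%s:%d: unknown panel attribute %r ignored",
                        source or "<string>", child.line.lineno, kw)
    if not shell:
        raise PCDParseError("panel requires a non-empty shell line",
                            line=node.line.lineno, source=source)
    return PanelSpec(tabs={k: tuple(v) for k, v in tabs.items()},
                     run_label=run_label, shell_template=shell)


def parse_menu(text: str, env: dict[str, str] | None = None, *,
               source: str | None = None) -> MenuSpec:
    """Parse PCD source text into a validated :class:`MenuSpec`.

    Parameters
    ----------
    text:
        The ``.blmenu`` file content. LF or CRLF line endings.
    env:
        Environment mapping used to expand ``$NAME`` references appearing
        in numeric attribute positions (min/max/default); references to
        unset variables are kept for later strict resolution, and all
        non-numeric ``$NAME`` references are retained verbatim.
    source:
        Optional path, recorded on the MenuSpec and in error messages.

    Raises
    ------
    PCDParseError
        On empty input, inconsistent indentation, unknown component
        keywords, duplicate var names, non-numeric bounds after
        expansion, or a chooser default that names no choice.
    """
    env = env or {}
    if not text or not text.strip():
        raise PCDParseError("empty menu source", source=source)
    roots = _build_blocks(_lex(text, source), source)

    title = icon = tip = None
    vars_: dict[str, VarSpec] = {}
    panels: list[PanelSpec] = []
    for node in roots:
        kw = node.line.keyword
        if kw == "name":
            title = _one_string_arg(node, source)
        elif kw == "icon":
            icon = _one_string_arg(node, source)
        elif kw == "tip":
            tip = _one_string_arg(node, source)
        elif kw == "var":
            spec = _parse_var(node, env, source)
            if any(spec.name.lower() == k.lower() for k in vars_):
                raise PCDParseError(f"duplicate var name {spec.name!r}",
                                    line=node.line.lineno, source=source)
            vars_[spec.name] = spec
        elif kw == "panel":
            names = {k.lower(): k for k in vars_}
            panels.append(_parse_panel(node, names, source))
        else:
            raise PCDParseError(f"unknown component keyword {kw!r}",
                                line=node.line.lineno, source=source)

    if title is None:
        raise PCDParseError("menu requires a name line", source=source)
    if not panels:
        raise PCDParseError("menu requires at least one panel", source=source)
    return MenuSpec(title=title, icon=icon or "", tip=tip or "",
                    vars=vars_, panels=tuple(panels), source=source or "")


# ---------------------------------------------------------------------------
# serialization


def _quote(text: str) -> str:
    escaped = (str(text).replace("\\", "\\\\").replace('"', '\\"')
               .replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t"))
    return '"' + escaped + '"'


def _render_scalar(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if isinstance(value, int) or value == int(value):
            return str(int(value))
        return repr(value)
    return _quote(str(value))


def serialize_menu(spec: MenuSpec) -> str:
    """Emit canonical PCD text; ``parse_menu(serialize_menu(s)) == s``."""
    out: list[str] = [f"name {_quote(spec.title)}"]
    if spec.icon:
        out.append(f"icon {_quote(spec.icon)}")
    if spec.tip:
        out.append(f"tip {_quote(spec.tip)}")
    for var in spec.vars.values():
        out.append(f"var {_quote(var.name)}")
        out.append(f"{INDENT}type {var.kind}")
        if var.label:
            out.append(f"{INDENT}label {_quote(var.label)}")
        if var.is_numeric:
            out.append(f"{INDENT}min {_render_scalar(var.min)}")
            out.append(f"{INDENT}default {_render_scalar(var.default)}")
            out.append(f"{INDENT}max {_render_scalar(var.max)}")
        elif var.default is not None:
            out.append(f"{INDENT}default {_render_scalar(var.default)}")
        if var.choices:
            out.append(f"{INDENT}choices")
            for label, fragment in var.choices.items():
                out.append(f"{INDENT * 2}{_quote(label)} {_quote(fragment)}")
        if var.kind == "tempfile":
            out.append(f"{INDENT}direction {var.direction}")
            if var.overwrite:
                out.append(f"{INDENT}overwrite true")
            out.append(f"{INDENT}format {var.format}")
    for panel in spec.panels:
        out.append("panel")
        if panel.run_label != "Run":
            out.append(f"{INDENT}runlabel {_quote(panel.run_label)}")
        for tab, members in panel.tabs.items():
            if tab == "":
                for member in members:
                    out.append(f"{INDENT}{_quote(member)}")
            else:
                out.append(f"{INDENT}tab {_quote(tab)}")
                for member in members:
                    out.append(f"{INDENT * 2}{_quote(member)}")
        out.append(f"{INDENT}shell {_quote(panel.shell_template)}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# placeholder validation


def iter_placeholders(text: str):
    """Yield placeholder names in ``text``, honoring the ``%%`` escape."""
    for name in PLACEHOLDER_RE.findall(text.replace("%%", "\x00")):
        yield name


def validate_placeholders(spec: MenuSpec) -> list[str]:
    """Return every ``%NAME%`` token that no var or reserved name resolves.

    Scans all shell templates and all chooser choice fragments. An empty
    list means the menu is fully resolvable.
    """
    known = {name.lower() for name in spec.vars}
    unresolved: list[str] = []
    texts = [p.shell_template for p in spec.panels]
    for var in spec.vars.values():
        texts.extend(var.choices.values())
    for text in texts:
        for name in iter_placeholders(text):
            if name.lower() in known or name in RESERVED_PLACEHOLDERS:
                continue
            if name not in unresolved:
                unresolved.append(name)
    return unresolved


__all__ = [
    "MenuSpec", "VarSpec", "PanelSpec", "parse_menu", "serialize_menu",
    "validate_placeholders", "iter_placeholders", "KINDS",
    "RESERVED_PLACEHOLDERS", "PLACEHOLDER_RE", "replace",
]
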