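"""Application definitions: Java-style ``.properties`` files.

An application is a canvas kind plus one or more PCD menu roots. The
definition lives in a ``.properties`` file whose ``pcd.menus.path`` key
holds a colon-separated, ``$VAR``-expandable list of menu root
directories, and whose ``canvas`` key names the canvas plugin
(``sequence``, ``table`` or ``image``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import AppError
from .menu_tree import MenuTree, load_menu_tree, parse_menus_path

CANVAS_KINDS = ("sequence", "table", "image")
MENUS_PATH_KEY = "pcd.menus.path"


def parse_properties(text: str) -> dict[str, str]:
    """Parse ``key=value`` lines; ``#`` lines are comments; later keys win."""
    props: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("!"):
            continue
        if "=" not in line:
            raise AppError(f"not a key=value line: {line!r}")
        key, _, value = line.partition("=")
        props[key.strip()] = value.strip()
    return props


@dataclass(frozen=True)
class AppDefinition:
    name: str
    properties: dict[str, str]
    menu_roots: tuple[str, ...]
    canvas_kind: str

    def load_tree(self, env: dict[str, str] | None = None) -> MenuTree:
        return load_menu_tree(self.menu_roots, env)


def load_app(properties_path, env: dict[str, str] | None = None) -> AppDefinition:
    """Read an application definition from a ``.properties`` file."""
    env = env or {}
    path = Path(properties_path)
    try:
        props = parse_properties(path.read_text())
    except OSError as exc:
        raise AppError(f"cannot read {path}: {exc}") from exc
    if MENUS_PATH_KEY not in props:
        raise AppError(f"{path}: missing required key {MENUS_PATH_KEY!r}")
    roots = tuple(parse_menus_path(props[MENUS_PATH_KEY], env))
    canvas = props.get("canvas", "")
    if canvas not in CANVAS_KINDS:
        raise AppError(f"{path}: unknown canvas kind {canvas!r} "
                       f"(expected one of {CANVAS_KINDS})")
    name = props.get("name", path.stem)
    return AppDefinition(name=name, properties=props, menu_roots=roots,
                         canvas_kind=canvas)


__all__ = ["AppDefinition", "load_app", "parse_properties", "CANVAS_KINDS",
           "MENUS_PATH_KEY"]
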