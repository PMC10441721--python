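"""Compose dropdown menu trees from PCD directory roots.

Dropdown menus are directories: each top-level folder under a PCD root
becomes one dropdown, named after the folder, and each ``.blmenu`` file
inside becomes one menu item. A plain-text ``pcd_order`` file fixes the
left-to-right order of dropdowns (at the root) or the top-to-bottom order
of items (inside a folder); names it does not mention are appended in
case-insensitive alphabetical order.

Several roots may be given (the ``pcd.menus.path`` mechanism, a
colon-separated list). Roots are read in order and a ``.blmenu`` file at
the same relative path as one already read supersedes it — this is how a
site layers local menu customizations over a stock installation without
touching it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .command_builder import expand_env
from .errors import MenuTreeError, PCDError
from .pcd_parser import MenuSpec, parse_menu

log = logging.getLogger(__name__)

ORDER_FILE = "pcd_order"
MENU_SUFFIX = ".blmenu"


@dataclass(frozen=True)
class DropdownMenu:
    name: str
    items: tuple[tuple[str, MenuSpec, str], ...]  # (item, spec, source root)

    def item(self, name: str) -> MenuSpec:
        for item_name, spec, _root in self.items:
            if item_name == name:
                return spec
        raise MenuTreeError(f"no item {name!r} in menu {self.name!r}")


@dataclass(frozen=True)
class MenuTree:
    menus: tuple[DropdownMenu, ...] = ()
    #: (path, message) for .blmenu files that failed to parse and were skipped
    errors: tuple[tuple[str, str], ...] = field(default=(), compare=False)

    def menu(self, name: str) -> DropdownMenu:
        for menu in self.menus:
            if menu.name == name:
                return menu
        raise MenuTreeError(f"no dropdown menu {name!r}")

    def find(self, ref: str) -> MenuSpec:
        """Resolve a ``Menu/item`` reference."""
        if "/" not in ref:
            raise MenuTreeError(f"expected Menu/item, got {ref!r}")
        menu, item = ref.split("/", 1)
        return self.menu(menu).item(item)


def order_items(entries, pcd_order_text: str | None):
    """Order ``entries`` by a ``pcd_order`` file's content.

    Names listed in the file come first, in file order; entries the file
    does not mention are appended in case-insensitive alphabetical order;
    listed names with no matching entry are skipped with a warning.
    """
    entries = list(entries)
    if pcd_order_text is None:
        return sorted(entries, key=str.lower)
    remaining = dict.fromkeys(entries)  # ordered set
    ordered = []
    for line in pcd_order_text.splitlines():
        name = line.strip()
        if not name or name.startswith("#"):
            continue
        if name in remaining:
            ordered.append(name)
            del remaining[name]
        else:
            log.warning("pcd_order names %r but no such entry exists", name)
    ordered.extend(sorted(remaining, key=str.lower))
    return ordered


def parse_menus_path(value: str, env: dict[str, str] | None = None) -> list[str]:
    """Split a ``pcd.menus.path`` value on ``:`` and expand ``$VAR`` refs.

    Order is preserved; a reference to an unset environment variable is an
    error naming the variable.
    """
    if not value:
        raise MenuTreeError("pcd.menus.path value is empty")
    env = env or {}
    return [expand_env(part, env) for part in value.split(":") if part]


def _read_order(directory: Path) -> str | None:
    path = directory / ORDER_FILE
    try:
        return path.read_text()
    except OSError:
        return None


def load_menu_tree(roots, env: dict[str, str] | None = None) -> MenuTree:
    """Load and compose the menu tree from one or more PCD roots.

    Later roots supersede earlier ones file-by-file (override identity is
    the path relative to the root). Dropdown order follows the first
    root that has a top-level ``pcd_order``; item order follows the
    folder's ``pcd_order`` (later roots may supersede that file too).
    A ``.blmenu`` file that fails to parse is recorded on the tree's
    ``errors`` and skipped; the tree still loads.
    """
    env = env or {}
    root_paths = [Path(r) for r in roots]
    readable = [r for r in root_paths if r.is_dir()]
    if not readable:
        raise MenuTreeError(f"no readable menu root among {list(map(str, root_paths))}")

    # relative path -> winning (root, absolute path); later roots win
    files: dict[str, tuple[Path, Path]] = {}
    orders: dict[str, str] = {}  # relative dir ("" = top) -> order text
    top_order: str | None = None
    for root in readable:
        if top_order is None:
            top_order = _read_order(root)
        for dropdown in sorted(p for p in root.iterdir() if p.is_dir()):
            rel_dir = dropdown.name
            order_text = _read_order(dropdown)
            if order_text is not None:
                orders[rel_dir] = order_text
            for path in sorted(dropdown.rglob("*" + MENU_SUFFIX)):
                rel = str(path.relative_to(root))
                files[rel] = (root, path)

    # group items per dropdown; nested subfolders flatten into the parent
    # dropdown with a "sub/name" item name
    by_menu: dict[str, dict[str, tuple[MenuSpec, str]]] = {}
    errors: list[tuple[str, str]] = []
    for rel, (root, path) in files.items():
        parts = Path(rel).parts
        dropdown = parts[0]
        item = "/".join(parts[1:])[: -len(MENU_SUFFIX)]
        try:
            spec = parse_menu(path.read_text(), env, source=str(path))
        except PCDError as exc:
            log.warning("skipping unparseable menu %s: %s", path, exc)
            errors.append((str(path), str(exc)))
            continue
        by_menu.setdefault(dropdown, {})[item] = (spec, str(root))

    menus = []
    for name in order_items(by_menu, top_order):
        items_map = by_menu[name]
        item_names = order_items(items_map, orders.get(name))
        items = tuple((item, *items_map[item]) for item in item_names)
        menus.append(DropdownMenu(name=name, items=items))
    return MenuTree(menus=tuple(menus), errors=tuple(errors))


__all__ = ["MenuTree", "DropdownMenu", "load_menu_tree", "order_items",
           "parse_menus_path"]
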