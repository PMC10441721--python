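"""Synthetic test material: menu corpora, a complete fixture application.

Everything here is deterministic per seed and self-contained — the
fixture application's "external programs" are tiny Python scripts written
next to the menus, so the full select/run/route cycle can be exercised
without any real bioinformatics tool installed.
"""

from __future__ import annotations

import random
import shutil
import string
import sys
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .canvases import SequenceCanvas, SequenceRecord, TableCanvas
from .pcd_parser import MenuSpec, PanelSpec, VarSpec, serialize_menu

#: tags used for deliberately malformed corpus entries
MALFORMED_TAGS = ("empty", "bad_indent", "duplicate_var", "unknown_keyword",
                  "broken_bounds", "bad_default")


def reference_menu_text() -> str:
    """The shipped window-shuffle reference menu, as PCD text."""
    return (resources.files("pcdlegato") / "data" / "shuffle.blmenu").read_text()


# ---------------------------------------------------------------------------
# random menu corpus


_WORDS = ("window", "gap", "matrix", "threads", "cutoff", "mode", "label",
          "alpha", "beta", "gamma", "delta", "strict", "wordsize", "evalue")


def _gen_valid_spec(rng: random.Random, index: int) -> MenuSpec:
    names = rng.sample(_WORDS, k=rng.randint(1, 4))
    vars_: dict[str, VarSpec] = {}
    out_var = None
    if rng.random() < 0.6:
        vars_["in1"] = VarSpec("in1", "tempfile", direction="in",
                               format=rng.choice(("fasta", "tsv", "text")))
        vars_["out1"] = VarSpec("out1", "tempfile", direction="out",
                                overwrite=rng.random() < 0.3, format="fasta")
        out_var = "out1"
    for name in names:
        kind = rng.choice(("text", "number", "slider", "chooser",
                           "choice-list", "file"))
        if kind in ("number", "slider"):
            lo = rng.randint(0, 5)
            hi = lo + rng.randint(1, 50)
            vars_[name] = VarSpec(name, kind, label=name.title(),
                                  min=lo, max=hi,
                                  default=rng.randint(lo, hi))
        elif kind in ("chooser", "choice-list"):
            labels = rng.sample(("Yes", "No", "Fast", "Slow", "Auto"),
                                k=rng.randint(1, 3))
            choices = {}
            for label in labels:
                if out_var and rng.random() < 0.4:
                    fragment = f"-o %{out_var}%"
                    if rng.random() < 0.3:
                        fragment += " %NEWINSTANCE%"
                else:
                    fragment = f"--{label.lower()}"
                choices[label] = fragment
            vars_[name] = VarSpec(name, kind, label=name.title(),
                                  default=rng.choice(labels), choices=choices)
        else:
            vars_[name] = VarSpec(name, kind, label=name.title(),
                                  default=rng.choice(("", "x", "out.txt")))
    pieces = [f"tool{index}"]
    for name in vars_:
        pieces.append(f"-{name[0]} %{name.upper() if rng.random() < 0.5 else name}%")
    if rng.random() < 0.2:
        pieces.append("--pct 50%%")
    settable = [n for n, v in vars_.items() if v.kind != "tempfile"]
    if settable and rng.random() < 0.5:
        half = max(1, len(settable) // 2)
        tabs = {"General": tuple(settable[:half]),
                "Output": tuple(settable[half:])} if len(settable) > 1 else \
               {"General": tuple(settable)}
        tabs = {k: v for k, v in tabs.items() if v}
    else:
        tabs = {"": tuple(settable)} if settable else {}
    panel = PanelSpec(tabs=tabs, shell_template=" ".join(pieces))
    return MenuSpec(title=f"Tool {index}",
                    icon="$BIRCH/images/tool.png" if rng.random() < 0.3 else "",
                    tip=f"Run tool {index}" if rng.random() < 0.5 else "",
                    vars=vars_, panels=(panel,))


def _gen_malformed(rng: random.Random, tag: str) -> str:
    name = rng.choice(_WORDS)
    if tag == "empty":
        return rng.choice(("", "   \n\n"))
    if tag == "bad_indent":
        return (f'name "Broken"\nvar "{name}"\n'
                '        type text\n    label "x"\n'
                'panel\n    shell "prog"\n')
    if tag == "duplicate_var":
        return (f'name "Broken"\nvar "{name}"\n    type text\n'
                f'var "{name}"\n    type text\n'
                'panel\n    shell "prog"\n')
    if tag == "unknown_keyword":
        return f'name "Broken"\nfrobnicate "x"\npanel\n    shell "prog"\n'
    if tag == "broken_bounds":
        return (f'name "Broken"\nvar "{name}"\n    type number\n'
                '    min 10\n    default 1\n    max 5\n'
                'panel\n    shell "prog"\n')
    if tag == "bad_default":
        return (f'name "Broken"\nvar "{name}"\n    type chooser\n'
                '    default "Nope"\n    choices\n'
                '        "Yes" "-y"\n        "No" "-n"\n'
                'panel\n    shell "prog"\n')
    raise ValueError(tag)


def gen_menu_corpus(n: int, seed: int):
    """Generate ``n`` corpus entries, mixing valid and malformed menus.

    Returns a list of ``(text, payload)`` where payload is the
    :class:`MenuSpec` the text serializes (valid entries) or a tag naming
    the planted defect (malformed entries). Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    corpus = []
    for i in range(n):
        if rng.random() < 0.7:
            spec = _gen_valid_spec(rng, i)
            corpus.append((serialize_menu(spec), spec))
        else:
            tag = rng.choice(MALFORMED_TAGS)
            corpus.append((_gen_malformed(rng, tag), tag))
    return corpus


# ---------------------------------------------------------------------------
# random canvases


def gen_sequence_canvas(rng: random.Random, n_records: int | None = None,
                        alphabet: str = "ACGT") -> SequenceCanvas:
    n = n_records if n_records is not None else rng.randint(1, 6)
    records = []
    for i in range(n):
        length = rng.randint(1, 120)
        residues = "".join(rng.choice(alphabet) for _ in range(length))
        desc = rng.choice(("", "synthetic record", f"locus {i}"))
        records.append(SequenceRecord(f"seq{i}", desc, residues))
    return SequenceCanvas(records=tuple(records))


def gen_table_canvas(rng: random.Random, n_rows: int | None = None) -> TableCanvas:
    n = n_rows if n_rows is not None else rng.randint(0, 20)
    n_cols = rng.randint(1, 5)
    columns = tuple(f"col{string.ascii_lowercase[i]}" for i in range(n_cols))
    rows = []
    for _ in range(n):
        row = []
        for _ in range(n_cols):
            if rng.random() < 0.4:
                row.append(str(rng.randint(-50, 5000)))
            else:
                row.append("".join(rng.choice(string.ascii_letters)
                                   for _ in range(rng.randint(0, 8))))
        rows.append(tuple(row))
    return TableCanvas(columns=columns, rows=tuple(rows))


# ---------------------------------------------------------------------------
# fixture application


_REVSEQ = '''\
#!/usr/bin/env python3
"""Toy fixture tool: reverse the residues of each FASTA record."""
import sys


def main():
    args = sys.argv[1:]
    out_path = args[args.index("-o") + 1]
    in_path = args[0]
    records = []
    header, seq = None, []
    with open(in_path) as fh:
        for line in fh:
            line = line.rstrip("\\n")
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(seq)))
                header, seq = line, []
            elif line:
                seq.append(line)
    if header is not None:
        records.append((header, "".join(seq)))
    with open(out_path, "w") as fh:
        for header, residues in records:
            fh.write(header + "\\n")
            rev = residues[::-1]
            for i in range(0, len(rev), 60):
                fh.write(rev[i:i + 60] + "\\n")


if __name__ == "__main__":
    main()
'''

_SHUFFLE = '''\
#!/usr/bin/env python3
"""Toy fixture tool: rotate each window-sized chunk of residues by one.

A deterministic stand-in for local shuffling: output length and
composition match the input, order differs within each window.
"""
import sys


def main():
    args = sys.argv[1:]
    in_path = args[0]
    window = int(args[args.index("-w") + 1])
    out_path = args[args.index("-o") + 1]
    records = []
    header, seq = None, []
    with open(in_path) as fh:
        for line in fh:
            line = line.rstrip("\\n")
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(seq)))
                header, seq = line, []
            elif line:
                seq.append(line)
    if header is not None:
        records.append((header, "".join(seq)))
    with open(out_path, "w") as fh:
        for header, residues in records:
            chunks = [residues[i:i + window]
                      for i in range(0, len(residues), window)]
            shuffled = "".join(c[1:] + c[:1] for c in chunks)
            fh.write(header + "\\n")
            for i in range(0, len(shuffled), 60):
                fh.write(shuffled[i:i + 60] + "\\n")


if __name__ == "__main__":
    main()
'''

_FIRST = '''\
#!/usr/bin/env python3
"""Toy fixture tool: keep only the first FASTA record."""
import sys


def main():
    args = sys.argv[1:]
    out_path = args[args.index("-o") + 1]
    in_path = args[0]
    out = []
    seen_headers = 0
    with open(in_path) as fh:
        for line in fh:
            if line.startswith(">"):
                seen_headers += 1
                if seen_headers > 1:
                    break
            out.append(line)
    with open(out_path, "w") as fh:
        fh.writelines(out)


if __name__ == "__main__":
    main()
'''

_PAIRS = '''\
#!/usr/bin/env python3
"""Toy fixture tool: pair R1/R2 read files listed in a one-column TSV."""
import sys

from pcdlegato.helpers import guess_pairs


def main():
    args = sys.argv[1:]
    out_path = args[args.index("-o") + 1]
    in_path = args[0]
    with open(in_path) as fh:
        lines = fh.read().splitlines()
    names = [line.split("\\t")[0] for line in lines[1:] if line]
    table = guess_pairs(names)
    with open(out_path, "w") as fh:
        fh.write("forward\\treverse\\n")
        for fwd, rev in table.rows:
            fh.write(f"{fwd}\\t{rev}\\n")


if __name__ == "__main__":
    main()
'''


def _menu(title: str, shell: str, *, tip: str = "", window_var: bool = False,
          out_format: str = "fasta", in_format: str = "fasta",
          overwrite: bool = False, chooser: bool = True,
          tempfiles: bool = True, default_choice: str = "New window") -> str:
    vars_: dict[str, VarSpec] = {}
    if window_var:
        vars_["window"] = VarSpec("window", "number", label="Window size",
                                  min=1, default=10, max=100)
    if tempfiles:
        vars_["in1"] = VarSpec("in1", "tempfile", direction="in",
                               format=in_format)
        vars_["out1"] = VarSpec("out1", "tempfile", direction="out",
                                overwrite=overwrite, format=out_format)
    if chooser:
        vars_["bloutput"] = VarSpec(
            "bloutput", "chooser", label="Output to new window?",
            default=default_choice,
            choices={"New window": "-o %out1% %NEWINSTANCE%",
                     "Current window": "-o %out1%"})
    settable = tuple(n for n, v in vars_.items() if v.kind != "tempfile")
    panel = PanelSpec(tabs={"": settable} if settable else {},
                      shell_template=shell)
    spec = MenuSpec(title=title, tip=tip, vars=vars_, panels=(panel,))
    return serialize_menu(spec)


@dataclass(frozen=True)
class FixtureApp:
    """A generated, self-contained application for end-to-end testing."""

    root: Path
    seed: int
    menus: int
    tools: tuple[str, ...]
    app_properties: Path        # sequence-canvas application (two roots)
    reads_properties: Path      # table-canvas application


def gen_fixture_app(directory, seed: int = 0) -> FixtureApp:
    """Write a complete fixture application under ``directory``.

    Layout: a ``base`` menu root, a ``local`` root that overrides the
    base shuffle menu (demonstrating later-root precedence), a ``reads``
    root for the table-canvas read-pairing demo, a ``tools`` directory of
    toy Python programs, and two ``.properties`` files. Regeneration into
    the same directory with the same seed is byte-identical.
    """
    root = Path(directory)
    if root.exists():
        shutil.rmtree(root)
    tools = root / "tools"
    tools.mkdir(parents=True)
    for name, text in (("revseq.py", _REVSEQ), ("shuffle.py", _SHUFFLE),
                       ("first_record.py", _FIRST), ("pairs_tool.py", _PAIRS)):
        path = tools / name
        path.write_text(text)
        path.chmod(0o755)

    py = sys.executable or "python3"

    def tool(name: str) -> str:
        return f"'{py}' '{tools / name}'"

    base = root / "base"
    local = root / "local"
    reads = root / "reads"
    menus = 0

    (base / "Similarity").mkdir(parents=True)
    (base / "Edit").mkdir(parents=True)
    (base / "pcd_order").write_text("Similarity\nEdit\n")
    (base / "Similarity" / "pcd_order").write_text("shuffle\n")
    (base / "Similarity" / "shuffle.blmenu").write_text(_menu(
        "Shuffle", f"{tool('shuffle.py')} %in1% -w %WINDOW% %BLOUTPUT%",
        tip="Randomize residues within a sliding window", window_var=True))
    menus += 1
    (base / "Edit" / "pcd_order").write_text("revseq\nfirst\nfail\n")
    (base / "Edit" / "revseq.blmenu").write_text(_menu(
        "Reverse", f"{tool('revseq.py')} %in1% %BLOUTPUT%",
        tip="Reverse each selected sequence"))
    (base / "Edit" / "first.blmenu").write_text(_menu(
        "First record", f"{tool('first_record.py')} %in1% -o %out1%",
        overwrite=True, chooser=False))
    (base / "Edit" / "fail.blmenu").write_text(_menu(
        "Always fails", "false", tempfiles=False, chooser=False))
    menus += 3

    (local / "Similarity").mkdir(parents=True)
    (local / "Similarity" / "shuffle.blmenu").write_text(_menu(
        "Shuffle (local)", f"{tool('shuffle.py')} %in1% -w %WINDOW% %BLOUTPUT%",
        tip="Site-customized shuffle", window_var=True))
    menus += 1

    (reads / "Files").mkdir(parents=True)
    (reads / "Files" / "guesspairs.blmenu").write_text(_menu(
        "Guess pairs", f"{tool('pairs_tool.py')} %in1% %BLOUTPUT%",
        tip="Pair forward/reverse read files on R1/R2",
        in_format="tsv", out_format="tsv"))
    menus += 1

    app_props = root / "app.properties"
    app_props.write_text(
        f"# generated fixture application (seed {seed})\n"
        "name=blseq\n"
        "canvas=sequence\n"
        f"pcd.menus.path={base}:{local}\n")
    reads_props = root / "reads.properties"
    reads_props.write_text(
        f"# generated fixture application (seed {seed})\n"
        "name=blreads\n"
        "canvas=table\n"
        f"pcd.menus.path={reads}\n")

    return FixtureApp(root=root, seed=seed, menus=menus,
                      tools=("revseq.py", "shuffle.py", "first_record.py",
                             "pairs_tool.py"),
                      app_properties=app_props, reads_properties=reads_props)


__all__ = ["FixtureApp", "gen_fixture_app", "gen_menu_corpus",
           "gen_sequence_canvas", "gen_table_canvas", "reference_menu_text",
           "MALFORMED_TAGS"]
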