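"""The full work cycle, twice: select, run a tool, work with the result.

Generates the self-contained fixture application (menus plus toy
external tools), loads a 3-record sequence canvas, runs the
sequence-reversing tool with new-instance routing, then runs it again on
the result — ad hoc pipelining. Reversal is an involution, so the final
canvas equals the original.
"""

import tempfile
from pathlib import Path

from pcdlegato import build_command, execute, load_menu_tree, read_fasta
from pcdlegato.fixtures import gen_fixture_app

workdir = Path(tempfile.mkdtemp(prefix="pcdlegato-demo-"))
app = gen_fixture_app(workdir / "app", seed=0)
tree = load_menu_tree([app.root / "base", app.root / "local"])

canvas = read_fasta(">a\nACGTAA\n>b\nGGCC\n>c\nTTTAC\n")
print("input:   ", [r.residues for r in canvas.records])

plan = build_command(tree.find("Edit/revseq"), {"bloutput": "New window"}, {})
result = execute(plan, canvas)
step1 = result.new_instances[0]
print("reversed:", [r.residues for r in step1.records],
      f"(exit {result.exit_code}, original canvas unchanged:"
      f" {not result.changed})")

plan = build_command(tree.find("Edit/revseq"), {"bloutput": "New window"}, {})
step2 = execute(plan, step1).new_instances[0]
print("again:   ", [r.residues for r in step2.records])
print("involution recovers the input:", step2.records == canvas.records)
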