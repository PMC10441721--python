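"""Parse the reference menu and build a command plan without executing.

Loads the shipped window-shuffle menu, lists its parameters, then
substitutes user values into the shell template — the headless
equivalent of filling in the menu and reading off the command the Run
button would execute.
"""

from pcdlegato import TempAllocator, build_command, parse_menu, validate_placeholders
from pcdlegato.fixtures import reference_menu_text

spec = parse_menu(reference_menu_text(), {})
print(f"menu: {spec.title!r}  tip: {spec.tip!r}")
for var in spec.vars.values():
    print(f"  var {var.name}: {var.kind}"
          + (f" [{var.min}..{var.max}] default {var.default}"
             if var.is_numeric else ""))
print("unresolved placeholders:", validate_placeholders(spec) or "none")

plan = build_command(spec, {"WINDOW": 25, "bloutput": "No"}, {},
                     TempAllocator("scratch-demo", seed=1))
print("\ncommand:", plan.command)
for name, (path, routing) in plan.temp_out.items():
    print(f"output {name} -> {path}  routing={routing}")
# The command is fully substituted (no %NAME% tokens remain); the out1
# path is where the program must write, and merge_current says its
# content would be appended to the current canvas after the run.
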