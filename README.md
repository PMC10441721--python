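# pcdlegato

A headless, testable engine for menu-driven wrapping of command-line
bioinformatics tools.

Many labs rely on a bench scientist being able to run BLAST, an
assembler, or a one-off script without memorizing its command syntax.
One proven way to provide that is a thin GUI layer that is *data-driven*:
every menu is a small text file declaring the tool's parameters and a
shell command template, and the application composes its menus at
runtime from directories of such files. Adding a tool means copying and
editing a text file — no compilation, no GUI programming.

`pcdlegato` implements that engine with no graphical toolkit anywhere,
for three audiences: tool wrappers who want to author and validate menu
files, bioinformaticians who want the same select → choose task → set
parameters → run → work-with-results cycle scriptable and pipeable from
Python or a shell, and anyone testing a menu corpus in CI.

## The model

- **PCD menus.** One `.blmenu` file defines one parameter menu: a
  title/icon/tool-tip, `var` declarations (text, number, slider,
  chooser, choice-list, file, tempfile widgets) and a `panel` whose
  `shell` line is a command template. The grammar is
  indentation-sensitive (see `docs/pcd-grammar.md`).
- **Substitution.** Each var's value replaces `%NAME%` in the template.
  A chooser substitutes the command *fragment* attached to the chosen
  label, and fragments may contain further placeholders — substitution
  runs to a fixed point, with cycle detection. `$NAME` environment
  references may appear anywhere (e.g. slider bounds set by a wrapper
  script). Tempfile vars substitute to freshly allocated paths.
- **Menu trees.** Directories become dropdown menus; `pcd_order` files
  fix ordering; several roots can be layered, with later roots
  superseding same-named files — local site customization without
  touching the base installation.
- **Canvases and routing.** Data lives in typed canvases (sequence,
  table). On a run, the selection is exported to the declared temp
  input files, the command executes under `sh`, and each temp output is
  routed back: merged into the current canvas, replacing it
  (`overwrite true`), or loaded into a new instance — which makes ad
  hoc pipelining (feeding one run's output into the next) a one-liner.

## Worked example

`examples/run_cycle.py` generates a self-contained fixture application
(menus wired to toy tools) and runs the sequence-reversing tool twice
with new-instance routing:

```
input:    ['ACGTAA', 'GGCC', 'TTTAC']
reversed: ['AATGCA', 'CCGG', 'CATTT'] (exit 0, original canvas unchanged: True)
again:    ['ACGTAA', 'GGCC', 'TTTAC']
involution recovers the input: True
```

Each line shows the residues of the three canvas records: the first run
produced a *new* canvas of reversed sequences and left the input canvas
untouched; running the same menu on that result reversed them back.

The same cycle from the shell:

```sh
pcdlegato fixtures --dir demo --seed 0
pcdlegato list --app demo/app.properties
pcdlegato run --app demo/app.properties Edit/revseq \
    --set 'bloutput=New window' --in in.fasta --out out.fasta
```

`pcdlegato run ... --dry-run` prints the fully substituted command and
its temp-file bindings as JSON without executing anything.

`examples/parse_and_build.py` and `examples/read_pairs_and_entrez.py`
demonstrate menu parsing/validation and the bundled helper computations
(R1/R2 read-pair guessing, assembler command-fragment dialects, Entrez
boolean query construction).

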