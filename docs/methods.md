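# Methods and design notes

## The engine in one paragraph

The package models a data-driven GUI layer for command-line tools,
minus the GUI. A menu is a text declaration (PCD) of parameters and a
shell command template; an application is a canvas kind plus a list of
menu directories; a run substitutes parameter values into the template,
executes it under the POSIX shell, and routes the declared output files
back into canvases. Every stage is a pure function over immutable data
(`MenuSpec` → `CommandPlan` → `RunResult`), which is what makes the
work cycle testable end to end without a display.

## The PCD dialect

The surface grammar (documented in `docs/pcd-grammar.md`) is this
package's own canonical dialect of the menu language: the keyword set
covers every construct the menu model needs — title/icon/tip lines,
seven widget kinds, choice fragments, tabbed panels, shell templates —
but no byte-compatibility with any other parser is claimed. Concrete
choices made where the design was open:

- **Indentation** is significant with tabs expanded to 8 columns and a
  consistent unit required per file. This keeps hand-written menus
  honest and makes "uniform re-indent parses equal" a testable
  invariant.
- **`%%`** escapes a literal percent sign; command lines for real tools
  contain percent signs, so an escape is unavoidable once `%NAME%` is
  claimed for placeholders.
- **Placeholder names match var names case-insensitively** (a var
  declared `window` is addressed as `%WINDOW%`), because menu authors
  conventionally uppercase placeholders in templates while declaring
  lowercase var names.
- **Unknown var/panel attributes warn and are ignored** (forward
  compatibility with richer dialects); unknown *top-level* component
  keywords are hard errors, since a skipped component would silently
  change a menu's meaning.
- **Unset `$NAME` in numeric bounds is not a parse error.** Bounds like
  a thread-slider's maximum are habitually supplied by the launching
  wrapper script; parse keeps the reference verbatim and
  `resolve_widget_bounds`/`build_command` resolve it strictly, naming
  the variable if it is still unset when a command is actually built.

## Substitution and routing

Substitution is a fixed-point iteration: each pass replaces every
resolvable `%NAME%` token at once — chooser tokens by their chosen
fragment (environment-expanded), scalars by rendered values (integers
without a decimal point; values containing whitespace shell-quoted),
tempfile tokens by lazily allocated paths `<workdir>/<var>-<8 hex>`.
Fragments introduce new tokens, so passes repeat; more passes than
declared vars plus one proves a fragment cycle, which is reported as a
typed error rather than looped on. Tokens no rule can replace are
reported together after the text stabilizes.

Routing per output tempfile: a fragment carrying the reserved
`%NEWINSTANCE%` marker routes the output files it references into a new
canvas; otherwise `overwrite true` selects replace-the-canvas and the
default is merge-append. The marker is this package's explicit,
machine-readable encoding of "this choice opens the result in a new
application window" — in a GUI that intent is expressed by launching a
viewer program inside the fragment, which a headless engine cannot
recognize reliably; the original GUI behavior of renaming a temp file so
the canvas re-reads it is likewise modeled as routing metadata rather
than an extra shell step, with the same observable effect.

The runtime runs `sh -c <command>` in the plan's private working
directory, captures both streams, and applies routing only on exit 0.
Canvases are frozen dataclasses, so atomicity on failure is structural:
there is no partially mutated state to roll back. Temp directories are
removed after the run unless `keep_temp` is set. An expected output
file that the program did not produce raises an error carrying a stderr
excerpt. The empty-selection policy defaults to select-all (the GUI
convenience norm) and is a flag.

## Menu trees

Override identity is the path relative to the root, because menus live
in per-dropdown subfolders. Dropdown order follows the first root's
top-level `pcd_order` (falling back to later roots', then to
case-insensitive alphabetical); item order follows the folder's
`pcd_order` with the same fallback, later roots superseding. Nested
subfolders below a dropdown are flattened into it with `sub/name` item
names. Non-menu files are ignored; an unparseable `.blmenu` is recorded
with its path on `MenuTree.errors` and skipped, so one broken menu
cannot take down an application.

## Canvases

Sequence I/O goes through Biopython (FASTA, 60-column wrap on write,
ids as the first header token, duplicates disambiguated by suffix with
a warning); tables are strict TSV (tabs in cells are errors) with
RFC-4180 CSV accepted on read via the standard `csv` module. Sorting is
stable with numeric-aware comparison — cells parsing as numbers sort
numerically and before text — and the selection follows the rows it
marked through the permutation. Coordinates are 0-based half-open;
sub-range selections export sliced residues. Gap characters pass
through untouched; alignment editing is out of scope. The image canvas
is a deliberate stub holding only a path.

## Helper computations

Read-pair guessing filters to `.fq`/`.fastq` extensions (the `fastq`
spelling accepted alongside the conventional `fq`), pairs on the *last*
occurrence of `R1`/`R2` so tokens elsewhere in a name do not mislead,
degrades unmatched files to single-end rows, and sorts by forward
filename; every read file appears exactly once in the output. Fragment
dialects render `-1/-2` flags (single-end: `-s`) or `q1 =`/`q2 =`
config lines (single-end: `q =`). The Entrez builder renders
`value [TAG]` terms joined by AND/OR/NOT with balanced parenthesis
counts per term; the molecule clause renders as
`AND biomol <molecule> [PROP]` and the length range as
`AND <min>:<max>[SLEN]` with no space before the bracket, mirroring the
Entrez range-field convention. The length range is an explicit optional
argument rather than a clause term, since it is a property of the
search as a whole.

## Fixtures and what they do and do not show

The fixture generators emulate the *mechanics* of a real menu corpus:
random valid menus across all widget kinds (serialized by the canonical
emitter), malformed menus with planted, tagged defects, and a complete
two-root application whose "external programs" are deterministic toy
Python scripts (sequence reverse, window rotation standing in for
shuffling, first-record extraction, read-pair tabulation, a
guaranteed-failing command). They are deterministic per seed and
regeneration is byte-identical. They do not emulate real tool behavior
— output volume, encodings, long runtimes, partial writes — so green
tests certify the engine's contracts (parsing, substitution, routing,
atomicity, ordering), not the behavior of any particular wrapped
program.

Problem sizes used by the test suite and the acceptance script — a
150-entry menu corpus, 100-canvas I/O round-trips, 3–5-record run
cycles, 1000-plan path-freshness checks — were chosen as the smallest
sizes at which the properties are meaningfully exercised; everything
completes in seconds.

## Known limitations

- The dialect is a reconstruction: menus written for the original
  Java-based parser are not guaranteed to parse byte-for-byte.
- Outputs are read whole after exit; nothing streams incrementally.
- Environment-variable values are not re-scanned for `%` tokens after
  expansion.
- One level of dropdown nesting is the intended layout; deeper levels
  flatten.
- No job control: no queueing, remote execution, or progress reporting.
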