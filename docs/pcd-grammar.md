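# The PCD menu grammar

One `.blmenu` file defines one parameter menu for one wrapped
command-line program. The shipped reference example is
`src/pcdlegato/data/shuffle.blmenu`.

## Lexical rules

- **Lines.** One statement per line. LF or CRLF accepted; the serializer
  emits LF. Blank lines and lines whose first non-blank character is `#`
  are ignored.
- **Indentation is significant.** Lines belonging to a component (a
  `var`, a `panel`, a `choices` block, a `tab`) are indented below it, in
  the way Python requires. Tabs count as 8 columns. All siblings under
  one parent must share the same indent level; the canonical form uses 4
  spaces per level, but any consistent unit parses. A uniform re-indent
  of a valid file parses to an equal menu.
- **Tokens.** A statement is a keyword followed by arguments. Arguments
  are either bare atoms (no whitespace or quotes) or double-quoted
  strings. Inside quotes, `\"`, `\\`, `\n`, `\r` and `\t` are escapes.
- **Placeholders.** `%NAME%` anywhere in a shell template or choice
  fragment is substituted at command-build time with the value of the
  var `NAME` (matched case-insensitively). `%%` is a literal percent
  sign. `%NEWINSTANCE%` is the single reserved placeholder: it
  substitutes to nothing and marks the fragment's output files for
  routing into a new application instance.
- **Environment references.** `$NAME` / `${NAME}` may appear anywhere.
  In numeric attribute positions (`min`, `max`, `default` of numeric
  vars) they are expanded at parse time when the variable is set, and
  kept for strict resolution at command-build time otherwise. Elsewhere
  they are retained verbatim and expanded when the command is built.

## Components

```
menu      := name-line [icon-line] [tip-line] var* panel+
name-line := "name" STRING
icon-line := "icon" STRING
tip-line  := "tip" STRING
```

### `var`

```
var STRING                      # the var's name
    type ATOM                   # text | number | slider | chooser |
                                # choice-list | file | tempfile
    label STRING                # optional; text shown to the user
    default VALUE               # see kind rules below
    min NUMBER|$REF             # numeric kinds only (required)
    max NUMBER|$REF             # numeric kinds only (required)
    choices                     # chooser kinds only (>= 1 entry)
        STRING STRING           # choice label, command fragment
    direction ATOM              # tempfile only: in | out | none
    overwrite ATOM              # tempfile out only: true | false
    format ATOM                 # tempfile: canvas export format
                                # (fasta | tsv | csv | text)
```

Kind rules:

- `number`, `slider` — `min`, `default`, `max` required; after
  environment expansion they must be numbers with
  `min <= default <= max`.
- `chooser`, `choice-list` — at least one choice; `default` must name a
  choice label (it defaults to the first one). The choice *fragment* is
  the text substituted for the var's placeholder and may itself contain
  placeholders (e.g. an output chooser whose fragment contains
  `%out1%`).
- `tempfile` — the var's placeholder substitutes to a freshly allocated
  temp-file path. `direction in` files receive the exported canvas
  selection (in `format`) before the run; `direction out` files are read
  back afterward. `overwrite true` (out only) replaces the entire canvas
  with the file's content instead of merging into it.

Var names are unique per menu (case-insensitively). Unknown attributes
are warned about and ignored; unknown top-level component keywords are
errors.

### `panel`

```
panel
    runlabel STRING             # optional, default "Run"
    tab STRING                  # optional grouping of parameters
        STRING                  # a var name per line
    STRING                      # var names directly under panel form
                                # a single unnamed tab
    shell STRING                # required, non-empty: the command
                                # template
```

Every var name listed in a tab must be declared. A menu may declare
several panels; the first is the default.
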