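"""Helper computations bundled with the demo applications.

Three small, self-contained utilities the shipped example menus use:

* :func:`guess_pairs` — pair forward/reverse sequencing-read files by the
  ``R1``/``R2`` naming convention, the way a read-file manager groups a
  directory listing before handing it to an assembler.
* :func:`pair_fragment` — render a read-pair table into the command
  syntax a given assembler dialect expects (``-1/-2`` flags on the
  command line, or ``q1 =``/``q2 =`` config-file lines).
* :func:`build_entrez_expression` — assemble an NCBI Entrez search
  expression from field-tagged terms, boolean operators and parenthesised
  groups. String construction only; nothing here talks to the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

READ_EXTENSIONS = (".fq", ".fastq")


@dataclass(frozen=True)
class ReadPairTable:
    """Rows of (forward, reverse) read files; reverse empty = single-end."""

    rows: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        seen: set[str] = set()
        for fwd, rev in self.rows:
            for name in (fwd, rev):
                if not name:
                    continue
                if name in seen:
                    raise ParameterError(f"filename appears twice: {name!r}")
                seen.add(name)


def _is_read_file(name: str) -> bool:
    return name.lower().endswith(READ_EXTENSIONS)


def guess_pairs(filenames) -> ReadPairTable:
    """Pair read files on the ``R1``/``R2`` tokens in their names.

    Only fastq files (``.fq``/``.fastq`` extension) appear in the output.
    A file containing ``R1`` (at its last occurrence) pairs with the file
    obtained by substituting ``R2`` there, when that file is present;
    files with neither token, or with an unmatched token, become
    single-end rows. Rows are sorted by forward filename. Every fastq
    input appears exactly once across the two columns.
    """
    reads = [name for name in filenames if _is_read_file(name)]
    present = set(reads)
    used: set[str] = set()
    rows: list[tuple[str, str]] = []
    for name in sorted(reads):
        if name in used:
            continue
        i = name.rfind("R1")
        if i >= 0:
            mate = name[:i] + "R2" + name[i + 2:]
            if mate in present and mate not in used:
                rows.append((name, mate))
                used.update((name, mate))
                continue
        j = name.rfind("R2")
        if j >= 0:
            mate = name[:j] + "R1" + name[j + 2:]
            if mate in present and mate not in used:
                rows.append((mate, name))
                used.update((name, mate))
                continue
        rows.append((name, ""))
        used.add(name)
    rows.sort(key=lambda r: r[0])
    return ReadPairTable(rows=tuple(rows))


def pair_fragment(table: ReadPairTable, dialect: str) -> str:
    """Render a read-pair table as a tool-specific command fragment.

    ``cli_flags`` emits ``-1 <fwd> -2 <rev>`` per pair (``-s <file>`` for
    single-end), space-joined on one line — the spades convention.
    ``config_lines`` emits ``q1 = <fwd>`` / ``q2 = <rev>`` line pairs
    (``q = <file>`` for single-end) — the SOAPdenovo2/Megahit config-file
    convention.
    """
    if dialect == "cli_flags":
        parts = []
        for fwd, rev in table.rows:
            parts.append(f"-1 {fwd} -2 {rev}" if rev else f"-s {fwd}")
        return " ".join(parts)
    if dialect == "config_lines":
        lines = []
        for fwd, rev in table.rows:
            if rev:
                lines.append(f"q1 = {fwd}")
                lines.append(f"q2 = {rev}")
            else:
                lines.append(f"q = {fwd}")
        return "\n".join(lines)
    raise ParameterError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class QueryClause:
    """A boolean Entrez query: field-tagged terms joined by operators.

    ``open_before[i]`` / ``close_after[i]`` count the parentheses opened
    before / closed after term *i*; they default to none.
    """

    terms: tuple[tuple[str, str], ...]            # (field tag, value)
    operators: tuple[str, ...] = ()               # AND | OR | NOT
    open_before: tuple[int, ...] = ()
    close_after: tuple[int, ...] = ()

    def __post_init__(self):
        n = len(self.terms)
        if n == 0:
            raise ParameterError("a query needs at least one term")
        if len(self.operators) != n - 1:
            raise ParameterError(
                f"{n} terms need {n - 1} operators, got {len(self.operators)}")
        for op in self.operators:
            if op not in ("AND", "OR", "NOT"):
                raise ParameterError(f"unknown operator {op!r}")
        opens = self.open_before or (0,) * n
        closes = self.close_after or (0,) * n
        if len(opens) != n or len(closes) != n:
            raise ParameterError("parenthesis markers must align with terms")
        depth = 0
        for i in range(n):
            depth += opens[i]
            depth -= closes[i]
            if depth < 0:
                raise ParameterError("unbalanced grouping: ')' before '('")
        if depth != 0:
            raise ParameterError("unbalanced grouping: unclosed '('")


def build_entrez_expression(clause: QueryClause,
                            molecule: str | None = None,
                            length_range: tuple[int, int] | None = None) -> str:
    """Render the clause as an Entrez search expression.

    Each term renders as ``value [TAG]``; operators are interleaved and
    groups parenthesised. A molecule type appends
    ``AND biomol <molecule> [PROP]`` and a length range appends
    ``AND <min>:<max>[SLEN]`` (no space before ``[SLEN]``, matching the
    Entrez convention for range fields).
    """
    n = len(clause.terms)
    opens = clause.open_before or (0,) * n
    closes = clause.close_after or (0,) * n
    parts = []
    for i, (tag, value) in enumerate(clause.terms):
        if i > 0:
            parts.append(clause.operators[i - 1])
        parts.append("(" * opens[i] + f"{value} [{tag}]" + ")" * closes[i])
    expr = " ".join(parts)
    if molecule:
        expr += f" AND biomol {molecule} [PROP]"
    if length_range:
        lo, hi = length_range
        expr += f" AND {lo}:{hi}[SLEN]"
    return expr


__all__ = ["ReadPairTable", "QueryClause", "guess_pairs", "pair_fragment",
           "build_entrez_expression", "READ_EXTENSIONS"]
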