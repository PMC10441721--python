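"""Typed data canvases: sequence, table, and a path-holding image stub.

A canvas is the in-memory object an application displays and operates
on. The engine is headless, so a canvas here is pure data plus the
operations the work cycle needs: selection, sorting, and text-format I/O
(FASTA for sequences; TSV, with CSV accepted on read, for tables).

Coordinates are 0-based and half-open everywhere. Gap characters (``-``)
in sequences are preserved verbatim by I/O; alignment editing is out of
the engine's core.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CanvasError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    residues: str


@dataclass(frozen=True)
class SequenceCanvas:
    """Ordered sequence records with a residue-range selection.

    ``selection`` holds ``(record_index, start, end)`` half-open residue
    ranges; a whole-record selection is ``(i, 0, len(residues))``.
    """

    records: tuple[SequenceRecord, ...] = ()
    selection: frozenset[tuple[int, int, int]] = frozenset()
    alphabet: str = "unchecked"  # nucleotide | protein | unchecked

    def __post_init__(self):
        for rec in self.records:
            if not rec.residues:
                raise CanvasError(f"record {rec.id!r} has no residues")
        for idx, start, end in self.selection:
            if not (0 <= idx < len(self.records)):
                raise CanvasError(f"selection names record {idx}, but canvas "
                                  f"has {len(self.records)} records")
            length = len(self.records[idx].residues)
            if not (0 <= start <= end <= length):
                raise CanvasError(
                    f"selection range [{start}, {end}) outside record "
                    f"{self.records[idx].id!r} of length {length}")

    def select_all(self) -> "SequenceCanvas":
        sel = frozenset((i, 0, len(r.residues))
                        for i, r in enumerate(self.records))
        return replace(self, selection=sel)

    def select_records(self, indices) -> "SequenceCanvas":
        sel = frozenset((i, 0, len(self.records[i].residues))
                        for i in indices)
        return replace(self, selection=sel)


@dataclass(frozen=True)
class TableCanvas:
    """A simple spreadsheet: columns, rows, a row selection, sort state."""

    columns: tuple[str, ...] = ()
    rows: tuple[tuple[str, ...], ...] = ()
    selection: frozenset[int] = frozenset()
    sort_state: tuple[str, bool] | None = None  # (column, ascending)

    def __post_init__(self):
        width = len(self.columns)
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise CanvasError(
                    f"row {i} has {len(row)} cells, expected {width}")
        for i in self.selection:
            if not (0 <= i < len(self.rows)):
                raise CanvasError(f"selected row {i} out of range")


@dataclass(frozen=True)
class ImageCanvas:
    """Stub: the image canvas only carries the path it would display."""

    image_path: str = ""


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(text: str) -> SequenceCanvas:
    """Parse FASTA text into a sequence canvas.

    Record ids are the first whitespace-delimited token after ``>``;
    duplicate ids are disambiguated by suffixing ``_2``, ``_3``, ... with
    a warning. Any line wrapping is accepted.
    """
    if not text.lstrip().startswith(">"):
        raise CanvasError("not FASTA: text does not start with '>'")
    seen: dict[str, int] = {}
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            log.warning("duplicate FASTA id %r renamed to %r", rid, new_id)
            rid = new_id
        else:
            seen[rec.id] = 1
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rid, desc, str(rec.seq)))
    if not records:
        raise CanvasError("no FASTA records found")
    return SequenceCanvas(records=tuple(records))


def write_fasta(canvas: SequenceCanvas) -> str:
    """Render all records as FASTA, wrapped at 60 columns."""
    out = io.StringIO()
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description=r.description)
            for r in canvas.records]
    SeqIO.write(seqs, out, "fasta")
    return out.getvalue()


# ---------------------------------------------------------------------------
# table I/O


def read_tsv(text: str) -> TableCanvas:
    """Parse TSV (first line header) into a table canvas."""
    lines = text.splitlines()
    if not lines:
        raise CanvasError("empty table text")
    columns = tuple(lines[0].split("\t"))
    rows = []
    for line in lines[1:]:
        if line == "" and len(columns) > 1:  # stray blank line, not a row
            continue
        cells = tuple(line.split("\t"))
        if len(cells) != len(columns):
            raise CanvasError(
                f"row has {len(cells)} cells, header has {len(columns)}")
        rows.append(cells)
    return TableCanvas(columns=columns, rows=tuple(rows))


def write_tsv(canvas: TableCanvas) -> str:
    """Render the table as TSV; a tab inside any cell is an error."""
    for row in (canvas.columns,) + canvas.rows:
        for cell in row:
            if "\t" in cell:
                raise CanvasError(f"cell contains a tab: {cell!r}")
            if "\n" in cell:
                raise CanvasError(f"cell contains a newline: {cell!r}")
    lines = ["\t".join(canvas.columns)]
    lines.extend("\t".join(row) for row in canvas.rows)
    return "\n".join(lines) + "\n"


def read_csv(text: str) -> TableCanvas:
    """Parse RFC-4180 CSV (first line header) into a table canvas."""
    reader = csv.reader(io.StringIO(text))
    try:
        columns = tuple(next(reader))
    except StopIteration:
        raise CanvasError("empty table text") from None
    rows = []
    for cells in reader:
        if not cells:
            continue
        if len(cells) != len(columns):
            raise CanvasError(
                f"row has {len(cells)} cells, header has {len(columns)}")
        rows.append(tuple(cells))
    return TableCanvas(columns=columns, rows=tuple(rows))


# ---------------------------------------------------------------------------
# table operations


def _sort_key(cell: str):
    # numeric-aware: cells that parse as numbers sort before text,
    # numerically among themselves
    try:
        return (0, float(cell), "")
    except ValueError:
        return (1, 0.0, cell)


def sort_table(canvas: TableCanvas, column: str,
               ascending: bool = True) -> TableCanvas:
    """Stable sort by one column; the selection follows its rows."""
    if column not in canvas.columns:
        raise CanvasError(f"unknown column {column!r}")
    ci = canvas.columns.index(column)
    order = sorted(range(len(canvas.rows)),
                   key=lambda i: _sort_key(canvas.rows[i][ci]),
                   reverse=not ascending)
    rows = tuple(canvas.rows[i] for i in order)
    new_pos = {old: new for new, old in enumerate(order)}
    selection = frozenset(new_pos[i] for i in canvas.selection)
    return TableCanvas(columns=canvas.columns, rows=rows,
                       selection=selection, sort_state=(column, ascending))


def select_rows(canvas: TableCanvas, selector=None, *,
                mode: str = "replace") -> TableCanvas:
    """Return the canvas with an updated row selection.

    ``selector`` is an iterable of row indices (a ``range`` works), a
    callable predicate over the row tuple, or ``None`` meaning all rows.
    ``mode`` is ``replace``, ``add``, ``toggle`` or ``clear``.
    """
    n = len(canvas.rows)
    if mode == "clear":
        return replace(canvas, selection=frozenset())
    if selector is None:
        picked = set(range(n))
    elif callable(selector):
        picked = {i for i, row in enumerate(canvas.rows) if selector(row)}
    else:
        picked = set(selector)
        for i in picked:
            if not (0 <= i < n):
                raise CanvasError(f"row index {i} out of range 0..{n - 1}")
    if mode == "replace":
        selection = frozenset(picked)
    elif mode == "add":
        selection = canvas.selection | picked
    elif mode == "toggle":
        selection = canvas.selection ^ picked
    else:
        raise CanvasError(f"unknown selection mode {mode!r}")
    return replace(canvas, selection=selection)


__all__ = [
    "SequenceRecord", "SequenceCanvas", "TableCanvas", "ImageCanvas",
    "read_fasta", "write_fasta", "read_tsv", "write_tsv", "read_csv",
    "sort_table", "select_rows",
]
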