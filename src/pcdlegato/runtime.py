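"""Execute a command plan against a canvas and route the outputs.

This is the run step of the work cycle: the current selection is
exported to each declared temp input file, the substituted command runs
under the POSIX shell in the plan's private working directory, and on
success each temp output file is read back and routed — merged into the
current canvas, replacing it, or loaded into a fresh canvas ("new
instance"). On any failure the caller's canvas is left untouched; canvas
objects are immutable, so the pre-run state can never be corrupted
half-way.
"""

from __future__ import annotations

import shutil
import subprocess
import time
from dataclasses import dataclass, field

from .canvases import (SequenceCanvas, TableCanvas, read_fasta, read_tsv,
                       write_fasta, write_tsv)
from .command_builder import (CommandPlan, MERGE_CURRENT, NEW_INSTANCE,
                              REPLACE_CURRENT)
from .errors import CanvasError, OutputMissingError


class _Unchanged:
    """Sentinel marking that a run left the current canvas as it was."""

    def __repr__(self):
        return "UNCHANGED"


UNCHANGED = _Unchanged()

Canvas = SequenceCanvas | TableCanvas


@dataclass(frozen=True)
class RunResult:
    """Outcome of one execution: status, streams, routed canvases."""

    exit_code: int
    stdout: str
    stderr: str
    updated_canvas: object = UNCHANGED  # Canvas or UNCHANGED
    new_instances: tuple[Canvas, ...] = ()
    elapsed: float = 0.0

    @property
    def changed(self) -> bool:
        return self.updated_canvas is not UNCHANGED


def export_selection(canvas: Canvas, format_tag: str, *,
                     select_all_if_empty: bool = True) -> str:
    """Serialize the canvas selection for hand-off to an external program.

    Sequence canvases export FASTA of the selected residue ranges (a
    sub-range selection exports just those residues of each record);
    table canvases export TSV (or CSV) of the selected rows, header
    included. An empty selection exports the whole canvas by default —
    the engine's select-all convenience policy.
    """
    if isinstance(canvas, SequenceCanvas):
        if format_tag not in ("fasta", "text"):
            raise CanvasError(
                f"sequence canvas cannot export format {format_tag!r}")
        work = canvas
        if not work.selection and select_all_if_empty:
            work = work.select_all()
        records = []
        for idx, start, end in sorted(work.selection):
            rec = work.records[idx]
            residues = rec.residues[start:end]
            if residues:
                records.append(type(rec)(rec.id, rec.description, residues))
        return write_fasta(SequenceCanvas(records=tuple(records)))
    if isinstance(canvas, TableCanvas):
        if format_tag not in ("tsv", "csv", "text"):
            raise CanvasError(
                f"table canvas cannot export format {format_tag!r}")
        indices = sorted(canvas.selection)
        if not indices and select_all_if_empty:
            indices = list(range(len(canvas.rows)))
        sub = TableCanvas(columns=canvas.columns,
                          rows=tuple(canvas.rows[i] for i in indices))
        if format_tag == "csv":
            import csv as _csv
            import io as _io
            buf = _io.StringIO()
            w = _csv.writer(buf)
            w.writerow(sub.columns)
            w.writerows(sub.rows)
            return buf.getvalue()
        return write_tsv(sub)
    raise CanvasError(f"cannot export canvas of type {type(canvas).__name__}")


def _parse_output(text: str, canvas: Canvas) -> Canvas:
    if isinstance(canvas, SequenceCanvas):
        return read_fasta(text)
    return read_tsv(text)


def execute(plan: CommandPlan, canvas: Canvas, *,
            keep_temp: bool = False, timeout: float | None = None,
            select_all_if_empty: bool = True) -> RunResult:
    """Run one command plan: export inputs, run ``sh -c``, route outputs.

    On a nonzero exit the result's canvas is the unchanged marker and no
    new instances are produced; the temp workdir is removed afterward
    unless ``keep_temp`` is set. A missing expected output raises
    :class:`OutputMissingError` carrying a stderr excerpt (the canvas is
    untouched in that case too).
    """
    plan.workdir.mkdir(parents=True, exist_ok=True)
    try:
        for name, (path, fmt) in plan.temp_in.items():
            path.write_text(
                export_selection(canvas, fmt,
                                 select_all_if_empty=select_all_if_empty))
        started = time.monotonic()
        proc = subprocess.run(["sh", "-c", plan.command], cwd=plan.workdir,
                              capture_output=True, text=True, timeout=timeout)
        elapsed = time.monotonic() - started
        if proc.returncode != 0:
            return RunResult(proc.returncode, proc.stdout, proc.stderr,
                             UNCHANGED, (), elapsed)

        current: Canvas | None = None  # None = untouched so far
        new_instances: list[Canvas] = []
        for name, (path, routing) in plan.temp_out.items():
            if not path.exists():
                raise OutputMissingError(path, proc.stderr)
            parsed = _parse_output(path.read_text(), canvas)
            if routing == NEW_INSTANCE:
                new_instances.append(parsed)
            elif routing == REPLACE_CURRENT:
                current = parsed
            elif routing == MERGE_CURRENT:
                base = current if current is not None else canvas
                current = _merge(base, parsed)
        return RunResult(proc.returncode, proc.stdout, proc.stderr,
                         current if current is not None else UNCHANGED,
                         tuple(new_instances), elapsed)
    finally:
        if not keep_temp:
            shutil.rmtree(plan.workdir, ignore_errors=True)


def _merge(base: Canvas, extra: Canvas) -> Canvas:
    if isinstance(base, SequenceCanvas) and isinstance(extra, SequenceCanvas):
        return SequenceCanvas(records=base.records + extra.records,
                              selection=base.selection,
                              alphabet=base.alphabet)
    if isinstance(base, TableCanvas) and isinstance(extra, TableCanvas):
        if extra.columns != base.columns:
            raise CanvasError("cannot merge tables with different columns: "
                              f"{base.columns} vs {extra.columns}")
        return TableCanvas(columns=base.columns, rows=base.rows + extra.rows,
                           selection=base.selection,
                           sort_state=None)
    raise CanvasError("cannot merge canvases of different types")


__all__ = ["RunResult", "UNCHANGED", "execute", "export_selection"]
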