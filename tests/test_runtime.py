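"""Execution runtime: export, subprocess run, output routing, atomicity."""

import pytest

from pcdlegato import (MenuSpec, PanelSpec, TableCanvas, TempAllocator,
                       UNCHANGED, VarSpec, build_command, execute,
                       export_selection, load_app, read_fasta, select_rows,
                       write_fasta)
from pcdlegato.errors import CanvasError, OutputMissingError


def plan_for(tree, ref, values, tmp_path, name="w"):
    spec = tree.find(ref)
    return build_command(spec, values, {}, TempAllocator(tmp_path / name))


@pytest.fixture()
def tree(fixture_app):
    return load_app(fixture_app.app_properties).load_tree()


# ---------------------------------------------------------------------------
# export_selection


def test_table_export_has_header_plus_selected_rows():
    canvas = TableCanvas(columns=("f",),
                         rows=(("a",), ("b",), ("c",), ("d",)))
    text = export_selection(select_rows(canvas, [1, 3]), "tsv")
    assert text.splitlines() == ["f", "b", "d"]


def test_empty_selection_exports_whole_canvas(three_seq_canvas):
    text = export_selection(three_seq_canvas, "fasta")
    assert text.count(">") == 3


def test_empty_selection_without_policy_exports_nothing(three_seq_canvas):
    text = export_selection(three_seq_canvas, "fasta",
                            select_all_if_empty=False)
    assert text == ""


def test_single_record_export_roundtrips(three_seq_canvas):
    canvas = three_seq_canvas.select_records([1])
    text = export_selection(canvas, "fasta")
    assert read_fasta(text).records[0].residues \
        == three_seq_canvas.records[1].residues


def test_subrange_selection_exports_sliced_residues(three_seq_canvas):
    canvas = type(three_seq_canvas)(records=three_seq_canvas.records,
                                    selection=frozenset({(0, 2, 6)}))
    exported = read_fasta(export_selection(canvas, "fasta"))
    assert exported.records[0].residues \
        == three_seq_canvas.records[0].residues[2:6]


def test_unsupported_format_tag_is_an_error(three_seq_canvas):
    with pytest.raises(CanvasError):
        export_selection(three_seq_canvas, "tsv")


# ---------------------------------------------------------------------------
# execute


def test_revseq_new_instance_leaves_original_untouched(tree, three_seq_canvas,
                                                       tmp_path):
    plan = plan_for(tree, "Edit/revseq", {"bloutput": "New window"}, tmp_path)
    result = execute(plan, three_seq_canvas)
    assert result.exit_code == 0
    assert result.updated_canvas is UNCHANGED
    assert len(result.new_instances) == 1
    reversed_ = [r.residues for r in result.new_instances[0].records]
    assert reversed_ == [r.residues[::-1] for r in three_seq_canvas.records]


def test_reverse_twice_is_the_identity(tree, three_seq_canvas, tmp_path):
    """Ad hoc pipelining: run 1's output is run 2's canvas."""
    first = execute(plan_for(tree, "Edit/revseq", {"bloutput": "New window"},
                             tmp_path, "a"), three_seq_canvas)
    second = execute(plan_for(tree, "Edit/revseq", {"bloutput": "New window"},
                              tmp_path, "b"), first.new_instances[0])
    assert second.new_instances[0].records == three_seq_canvas.records


def test_merge_routing_appends_to_current_canvas(tree, three_seq_canvas,
                                                 tmp_path):
    plan = plan_for(tree, "Edit/revseq", {"bloutput": "Current window"},
                    tmp_path)
    result = execute(plan, three_seq_canvas)
    assert result.new_instances == ()
    merged = result.updated_canvas
    assert len(merged.records) == 6
    assert merged.records[:3] == three_seq_canvas.records


def test_replace_routing_with_overwrite_true(tree, tmp_path, rng):
    """A 5-record canvas replaced by a 1-record program output."""
    text = "".join(f">s{i}\nACGTAC\n" for i in range(5))
    canvas = read_fasta(text)
    result = execute(plan_for(tree, "Edit/first", {}, tmp_path), canvas)
    assert result.changed
    assert len(result.updated_canvas.records) == 1
    assert result.updated_canvas.records[0].id == "s0"


def test_failing_command_leaves_canvas_byte_identical(tree, three_seq_canvas,
                                                      tmp_path):
    before = write_fasta(three_seq_canvas)
    result = execute(plan_for(tree, "Edit/fail", {}, tmp_path),
                     three_seq_canvas)
    assert result.exit_code == 1
    assert result.updated_canvas is UNCHANGED
    assert result.new_instances == ()
    assert write_fasta(three_seq_canvas) == before


def test_missing_output_file_is_reported_with_stderr(three_seq_canvas,
                                                     tmp_path):
    spec = MenuSpec(
        title="NoOutput",
        vars={"out1": VarSpec("out1", "tempfile", direction="out")},
        panels=(PanelSpec(
            shell_template="echo oops >&2; true # %out1%"),))
    plan = build_command(spec, {}, {}, TempAllocator(tmp_path / "w"))
    with pytest.raises(OutputMissingError, match="oops"):
        execute(plan, three_seq_canvas)


def test_workdir_removed_after_success_kept_on_request(tree, three_seq_canvas,
                                                       tmp_path):
    plan = plan_for(tree, "Edit/revseq", {"bloutput": "New window"},
                    tmp_path, "gone")
    execute(plan, three_seq_canvas)
    assert not plan.workdir.exists()
    plan2 = plan_for(tree, "Edit/revseq", {"bloutput": "New window"},
                     tmp_path, "kept")
    execute(plan2, three_seq_canvas, keep_temp=True)
    assert plan2.workdir.exists()
    assert any(plan2.workdir.iterdir())


def test_stdout_and_stderr_are_captured(three_seq_canvas, tmp_path):
    spec = MenuSpec(title="Echo", panels=(PanelSpec(
        shell_template="echo hello; echo warn >&2"),))
    plan = build_command(spec, {}, {}, TempAllocator(tmp_path / "w"))
    result = execute(plan, three_seq_canvas)
    assert result.stdout.strip() == "hello"
    assert result.stderr.strip() == "warn"
    assert result.elapsed >= 0


def test_window_shuffle_preserves_composition(tree, three_seq_canvas,
                                              tmp_path):
    """The shuffle tool permutes within windows: same residue counts."""
    plan = plan_for(tree, "Similarity/shuffle",
                    {"WINDOW": 4, "bloutput": "New window"}, tmp_path)
    result = execute(plan, three_seq_canvas)
    out = result.new_instances[0]
    for before, after in zip(three_seq_canvas.records, out.records):
        assert sorted(before.residues) == sorted(after.residues)
        assert len(before.residues) == len(after.residues)
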