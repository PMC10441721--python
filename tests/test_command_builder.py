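"""Command building: env expansion, fixpoint substitution, routing."""

import re
import tempfile
from pathlib import Path

import pytest

from pcdlegato import (MenuSpec, PanelSpec, TempAllocator, VarSpec,
                       build_command, expand_env, resolve_widget_bounds)
from pcdlegato.command_builder import (MERGE_CURRENT, NEW_INSTANCE,
                                       REPLACE_CURRENT)
from pcdlegato.errors import (ParameterError, PlaceholderError,
                              SubstitutionCycleError, UnsetVariableError)
from pcdlegato.pcd_parser import PLACEHOLDER_RE


def make_spec(shell, **vars_):
    return MenuSpec(title="T", vars=vars_,
                    panels=(PanelSpec(shell_template=shell),))


def alloc(tmp_path, seed=1):
    return TempAllocator(tmp_path / "work", seed=seed)


# ---------------------------------------------------------------------------
# expand_env


@pytest.mark.parametrize("text,env,expected", [
    ("$BIRCH/dat/icon.png", {"BIRCH": "/opt/birch"}, "/opt/birch/dat/icon.png"),
    ("${BIRCH}/dat", {"BIRCH": "/opt/birch"}, "/opt/birch/dat"),
    ("no refs here", {}, "no refs here"),
    ("keep %NAME% alone $X", {"X": "v"}, "keep %NAME% alone v"),
])
def test_expand_env(text, env, expected):
    assert expand_env(text, env) == expected


def test_expand_env_unset_names_the_variable():
    with pytest.raises(UnsetVariableError, match="MISSING"):
        expand_env("$MISSING", {})


# ---------------------------------------------------------------------------
# build_command


def test_shuffle_no_branch_two_pass_oracle(shuffle_spec, tmp_path):
    """Manual two-pass substitution: chooser fragment first, then paths."""
    a = alloc(tmp_path)
    plan = build_command(shuffle_spec, {"WINDOW": 10, "bloutput": "No"}, {}, a)
    in1, _ = plan.temp_in["in1"]
    out1, routing = plan.temp_out["out1"]
    assert plan.command == f"shuffle.py {in1} -w 10 -o {out1}"
    assert routing == MERGE_CURRENT
    assert in1.parent == plan.workdir and out1.parent == plan.workdir
    assert in1 != out1


def test_shuffle_yes_branch_routes_new_instance(shuffle_spec, tmp_path):
    plan = build_command(shuffle_spec, {"WINDOW": 10, "bloutput": "Yes"}, {},
                         alloc(tmp_path))
    _, routing = plan.temp_out["out1"]
    assert routing == NEW_INSTANCE
    assert not PLACEHOLDER_RE.search(plan.command)


def test_both_branches_leave_no_placeholder_tokens(shuffle_spec, tmp_path):
    for choice in ("Yes", "No"):
        plan = build_command(shuffle_spec,
                             {"WINDOW": 3, "bloutput": choice}, {},
                             alloc(tmp_path / choice))
        assert not re.search(r"%[A-Za-z0-9_]+%", plan.command)


def test_template_without_placeholders_is_untouched(tmp_path):
    spec = make_spec("prog --fixed")
    plan = build_command(spec, {}, {}, alloc(tmp_path))
    assert plan.command == "prog --fixed"
    assert plan.temp_in == {} and plan.temp_out == {}


def test_two_fragment_cycle_is_detected(tmp_path):
    spec = make_spec(
        "prog %A%",
        A=VarSpec("A", "chooser", default="x", choices={"x": "%B%"}),
        B=VarSpec("B", "chooser", default="y", choices={"y": "%A%"}))
    with pytest.raises(SubstitutionCycleError):
        build_command(spec, {}, {}, alloc(tmp_path))


def test_self_referencing_fragment_is_a_cycle(tmp_path):
    spec = make_spec(
        "prog %A%",
        A=VarSpec("A", "chooser", default="x", choices={"x": "%A%"}))
    with pytest.raises(SubstitutionCycleError):
        build_command(spec, {}, {}, alloc(tmp_path))


def test_undefined_placeholder_after_fixpoint(tmp_path):
    spec = make_spec("prog %FOO%")
    with pytest.raises(PlaceholderError, match="FOO"):
        build_command(spec, {}, {}, alloc(tmp_path))


def test_value_out_of_range_rejected(shuffle_spec, tmp_path):
    with pytest.raises(ParameterError, match="outside"):
        build_command(shuffle_spec, {"WINDOW": 1000}, {}, alloc(tmp_path))


def test_unknown_parameter_rejected(shuffle_spec, tmp_path):
    with pytest.raises(ParameterError, match="unknown parameter"):
        build_command(shuffle_spec, {"nope": 1}, {}, alloc(tmp_path))


def test_chooser_value_must_name_a_choice(shuffle_spec, tmp_path):
    with pytest.raises(ParameterError):
        build_command(shuffle_spec, {"bloutput": "Maybe"}, {}, alloc(tmp_path))


def test_values_with_whitespace_are_shell_quoted(tmp_path):
    spec = make_spec("prog -t %TITLE%",
                     TITLE=VarSpec("TITLE", "text", default=""))
    plan = build_command(spec, {"TITLE": "two words"}, {}, alloc(tmp_path))
    assert plan.command == "prog -t 'two words'"


def test_percent_escape_survives_substitution(tmp_path):
    spec = make_spec("prog --pct 50%% -w %W%",
                     W=VarSpec("W", "number", min=1, default=2, max=9))
    plan = build_command(spec, {}, {}, alloc(tmp_path))
    assert plan.command == "prog --pct 50% -w 2"


def test_integer_values_render_without_decimal_point(tmp_path):
    spec = make_spec("prog -w %W%",
                     W=VarSpec("W", "number", min=0, default=5.0, max=9))
    plan = build_command(spec, {"W": "7"}, {}, alloc(tmp_path))
    assert plan.command.endswith("-w 7")


def test_overwrite_out_var_routes_replace(tmp_path):
    spec = make_spec("prog %in1% -o %out1%",
                     in1=VarSpec("in1", "tempfile", direction="in",
                                 format="fasta"),
                     out1=VarSpec("out1", "tempfile", direction="out",
                                  overwrite=True))
    plan = build_command(spec, {}, {}, alloc(tmp_path))
    assert plan.temp_out["out1"][1] == REPLACE_CURRENT


def test_building_twice_with_same_allocator_seed_is_identical(shuffle_spec,
                                                              tmp_path):
    plans = [build_command(shuffle_spec, {"WINDOW": 10, "bloutput": "No"}, {},
                           TempAllocator(tmp_path / "w", seed=42))
             for _ in range(2)]
    assert plans[0] == plans[1]


def test_temp_paths_fresh_across_many_plans(shuffle_spec):
    paths = set()
    for _ in range(1000):
        workdir = Path(tempfile.mkdtemp(prefix="pcdl-fresh-"))
        plan = build_command(shuffle_spec, {"bloutput": "No"}, {},
                             TempAllocator(workdir))
        for p, _tag in list(plan.temp_in.values()) + list(plan.temp_out.values()):
            assert p not in paths
            paths.add(p)
        workdir.rmdir()
    assert len(paths) == 2000


# ---------------------------------------------------------------------------
# resolve_widget_bounds


def test_slider_bounds_from_environment():
    var = VarSpec("threads", "slider", min=1, default="$BL_CORES_DEFAULT",
                  max="$BL_CORES_MAX")
    resolved = resolve_widget_bounds(
        var, {"BL_CORES_MAX": "8", "BL_CORES_DEFAULT": "2"})
    assert (resolved.min, resolved.default, resolved.max) == (1, 2, 8)


def test_literal_bounds_pass_through():
    var = VarSpec("w", "number", min=1, default=10, max=100)
    assert resolve_widget_bounds(var, {}) == var


def test_non_numeric_environment_bound_is_an_error():
    var = VarSpec("threads", "slider", min=1, default=2, max="$BL_CORES_MAX")
    with pytest.raises(ParameterError, match="not numeric"):
        resolve_widget_bounds(var, {"BL_CORES_MAX": "many"})


def test_violated_ordering_is_an_error():
    var = VarSpec("w", "slider", min=5, default=10, max="$M")
    with pytest.raises(ParameterError, match="fails"):
        resolve_widget_bounds(var, {"M": "7"})
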