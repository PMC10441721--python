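"""Parser and serializer: grammar, validation, round-trip identity."""

import pytest
from hypothesis import given, settings, strategies as st

from pcdlegato import (MenuSpec, PanelSpec, VarSpec, parse_menu,
                       serialize_menu, validate_placeholders)
from pcdlegato.errors import PCDParseError
from pcdlegato.fixtures import MALFORMED_TAGS, gen_menu_corpus

MINIMAL = '''\
name "Minimal"
var "WINDOW"
    type number
    min 1
    default 10
    max 100
panel
    shell "prog -w %WINDOW%"
'''


def test_minimal_menu_hand_parse():
    """The minimal source parses to exactly what a hand parse gives."""
    spec = parse_menu(MINIMAL, {})
    assert spec.title == "Minimal"
    assert list(spec.vars) == ["WINDOW"]
    var = spec.vars["WINDOW"]
    assert (var.kind, var.min, var.default, var.max) == ("number", 1, 10, 100)
    assert len(spec.panels) == 1
    assert spec.panels[0].shell_template == "prog -w %WINDOW%"


@pytest.mark.parametrize("text", ["", "   \n\t\n"])
def test_empty_input_is_a_parse_error(text):
    with pytest.raises(PCDParseError):
        parse_menu(text, {})


def test_reference_menu_declares_the_expected_vars(shuffle_spec):
    assert list(shuffle_spec.vars) == ["window", "in1", "out1", "bloutput"]
    assert shuffle_spec.title == "Shuffle"
    assert "$BIRCH" in shuffle_spec.icon  # env refs retained verbatim
    assert shuffle_spec.vars["bloutput"].choices["No"] == "-o %out1%"


def test_unresolved_env_bounds_are_retained():
    text = MINIMAL.replace("max 100", 'max "$BL_CORES_MAX"')
    spec = parse_menu(text, {})
    assert spec.vars["WINDOW"].max == "$BL_CORES_MAX"
    # and expanded when the variable is set
    spec2 = parse_menu(text, {"BL_CORES_MAX": "16"})
    assert spec2.vars["WINDOW"].max == 16


def test_env_expansion_applies_before_numeric_validation():
    text = MINIMAL.replace("max 100", 'max "$M"')
    with pytest.raises(PCDParseError):
        parse_menu(text, {"M": "5"})  # 10 > 5 violates min<=default<=max


@pytest.mark.parametrize("mutate,match", [
    (lambda t: t.replace('var "WINDOW"', 'frob "WINDOW"'), "unknown component"),
    (lambda t: t + 'var "WINDOW"\n    type text\n', "duplicate var"),
    (lambda t: t.replace("default 10", 'default "ten"'), "not a number"),
    (lambda t: t.replace("    min 1", "  min 1"), "indent"),
    (lambda t: t.replace('    shell "prog -w %WINDOW%"', "    shell"),
     "exactly one value"),
])
def test_malformed_sources_raise_typed_errors(mutate, match):
    with pytest.raises(PCDParseError, match=match):
        parse_menu(mutate(MINIMAL), {})


def test_chooser_default_must_name_a_choice():
    text = ('name "X"\nvar "c"\n    type chooser\n    default "Q"\n'
            '    choices\n        "Yes" "-y"\n'
            'panel\n    shell "prog %c%"\n')
    with pytest.raises(PCDParseError, match="not a choice label"):
        parse_menu(text, {})


def test_overwrite_restricted_to_out_tempfiles():
    text = ('name "X"\nvar "t"\n    type tempfile\n    direction in\n'
            '    overwrite true\npanel\n    shell "prog %t%"\n')
    with pytest.raises(PCDParseError, match="overwrite"):
        parse_menu(text, {})


def test_roundtrip_on_generated_corpus():
    """parse∘serialize is the identity on >=50 generated valid menus."""
    corpus = gen_menu_corpus(120, seed=11)
    valid = [(text, spec) for text, spec in corpus
             if isinstance(spec, MenuSpec)]
    assert len(valid) >= 50
    for text, spec in valid:
        assert parse_menu(text, {}) == spec
        assert parse_menu(serialize_menu(spec), {}) == spec


def test_malformed_corpus_raises_typed_errors_only():
    corpus = gen_menu_corpus(120, seed=11)
    tagged = [(text, tag) for text, tag in corpus if isinstance(tag, str)]
    assert {tag for _, tag in tagged} <= set(MALFORMED_TAGS)
    for text, tag in tagged:
        with pytest.raises(PCDParseError):
            parse_menu(text, {})


def test_uniform_reindentation_is_equivalent(shuffle_text, shuffle_spec):
    """Re-indenting 4 -> 8 spaces parses to an equal menu."""
    reindented = "\n".join(
        line.replace("    ", "        ", 1) if line.startswith("    ")
        else line
        for line in shuffle_text.splitlines())
    reindented = reindented.replace("        " * 2, "                ")
    assert parse_menu(reindented, {}) == shuffle_spec


def test_tabs_count_as_eight_columns(shuffle_text, shuffle_spec):
    tabbed = "\n".join(
        "\t" + line[4:] if line.startswith("    ") else line
        for line in shuffle_text.splitlines())
    assert parse_menu(tabbed, {}) == shuffle_spec


def test_tab_blocks_serialize_in_declaration_order():
    spec = MenuSpec(
        title="T",
        vars={"a": VarSpec("a", "text"), "b": VarSpec("b", "text")},
        panels=(PanelSpec(tabs={"Second": ("b",), "First": ("a",)},
                          shell_template="prog %a% %b%"),))
    text = serialize_menu(spec)
    assert text.index('tab "Second"') < text.index('tab "First"')
    assert list(parse_menu(text, {}).panels[0].tabs) == ["Second", "First"]


def test_serializer_leaves_fragment_placeholders_untouched():
    spec = MenuSpec(
        title="T",
        vars={"out1": VarSpec("out1", "tempfile", direction="out"),
              "c": VarSpec("c", "chooser", default="No",
                           choices={"No": "-o %out1%"})},
        panels=(PanelSpec(shell_template="prog %c%"),))
    assert '"-o %out1%"' in serialize_menu(spec)


@pytest.mark.parametrize("template,expected", [
    ("prog -w %WINDOW% -i %in1% %BLOUTPUT%", []),
    ("prog %FOO%", ["FOO"]),
    ("prog --plain", []),
    ("prog --pct 50%% %FOO%", ["FOO"]),
])
def test_validate_placeholders(shuffle_spec, template, expected):
    spec = MenuSpec(title=shuffle_spec.title, vars=shuffle_spec.vars,
                    panels=(PanelSpec(shell_template=template),))
    assert validate_placeholders(spec) == expected


def test_reference_menu_is_fully_resolvable(shuffle_spec):
    assert validate_placeholders(shuffle_spec) == []


@settings(derandomize=True, max_examples=60, deadline=None)
@given(title=st.text(min_size=1).filter(lambda s: s.strip()),
       label=st.text())
def test_string_quoting_roundtrips_arbitrary_text(title, label):
    """Titles and labels with quotes/backslashes survive serialization."""
    spec = MenuSpec(title=title,
                    vars={"v": VarSpec("v", "text", label=label, default="")},
                    panels=(PanelSpec(shell_template="prog %v%"),))
    assert parse_menu(serialize_menu(spec), {}) == spec
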