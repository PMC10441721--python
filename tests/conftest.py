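import random

import pytest

from pcdlegato import parse_menu, read_fasta
from pcdlegato.fixtures import gen_fixture_app, reference_menu_text


@pytest.fixture(scope="session")
def shuffle_text() -> str:
    return reference_menu_text()


@pytest.fixture(scope="session")
def shuffle_spec(shuffle_text):
    return parse_menu(shuffle_text, {})


@pytest.fixture(scope="session")
def fixture_app(tmp_path_factory):
    return gen_fixture_app(tmp_path_factory.mktemp("fixapp") / "app", seed=0)


@pytest.fixture()
def three_seq_canvas():
    return read_fasta(">a first\nACGTACGT\n>b\nGGCCTTAA\n>c\nAAACCC\n")


@pytest.fixture()
def rng():
    return random.Random(20_240_901)
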