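import pytest

from phenoxp import fixtures as fx
from phenoxp.label_grammar import build_lexicon


@pytest.fixture(scope="session")
def paper_fixture():
    return fx.build_paper_fixture()


@pytest.fixture(scope="session")
def paper_lexicon(paper_fixture):
    return build_lexicon(paper_fixture.lexicon_inputs())


@pytest.fixture(scope="session")
def paper_labels(paper_fixture):
    return paper_fixture.labels()
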