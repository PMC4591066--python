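import pytest

from toolfinder import (EdamRecognizer, FixtureSpec, LexiconRecognizer,
                        QUESTION_1, QUESTION_2, TermIndex, discover,
                        interpret, load_lexicon, load_obo, load_repository,
                        write_fixtures)


@pytest.fixture(scope="session")
def fxdir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    write_fixtures(d, FixtureSpec(seed=1))
    return d


@pytest.fixture(scope="session")
def index(fxdir):
    return TermIndex(load_obo(fxdir / "mini.obo"))


@pytest.fixture(scope="session")
def lexicon(fxdir):
    return load_lexicon(fxdir / "lexicon.tsv")


@pytest.fixture(scope="session")
def repo(fxdir, index, lexicon):
    r = load_repository(fxdir / "tools.json")
    r.annotate_all(EdamRecognizer(index), LexiconRecognizer(lexicon))
    return r


@pytest.fixture(scope="session")
def q1_result(index, lexicon, repo):
    return discover(interpret(QUESTION_1, index, lexicon), repo)


@pytest.fixture(scope="session")
def q2_result(index, lexicon, repo):
    return discover(interpret(QUESTION_2, index, lexicon), repo)
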