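import pytest

import propsel as ps


@pytest.fixture(scope="session")
def mito_code():
    return ps.GeneticCode.vertebrate_mitochondrial()


@pytest.fixture(scope="session")
def std_code():
    return ps.GeneticCode.standard()


@pytest.fixture(scope="session")
def default_table():
    return ps.load_default_properties()


@pytest.fixture(scope="session")
def mito_neighborhood(mito_code):
    return ps.build_neighborhood(mito_code)


@pytest.fixture(scope="session")
def null_model(default_table, mito_neighborhood):
    """Neutral reference for the bundled 20 properties, mitochondrial code."""
    return ps.NullModel.build(default_table, mito_neighborhood)


@pytest.fixture
def quartet_tree():
    return ps.Phylogeny.from_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")


def make_alignment(seqs: dict[str, str]) -> ps.CodonAlignment:
    return ps.CodonAlignment(taxa=list(seqs), sequences=list(seqs.values()))


@pytest.fixture
def star8_newick():
    return "(a:0.3,b:0.3,c:0.3,d:0.3,e:0.3,f:0.3,g:0.3,h:0.3);"
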