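import pytest

from a3splice.gene_models import build_junction_probes, paralog_fixture


@pytest.fixture(scope="session")
def fixture_models():
    """The default two-paralog gene/isoform fixture (deterministic)."""
    return paralog_fixture()


@pytest.fixture(scope="session")
def genes(fixture_models):
    return fixture_models[0]


@pytest.fixture(scope="session")
def isoforms(fixture_models):
    return fixture_models[1]


@pytest.fixture(scope="session")
def probes(genes, isoforms):
    return build_junction_probes(isoforms.values(), genes, flank_len=39)
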