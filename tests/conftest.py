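import pytest

from epimir import (
    consensus_interactions,
    filter_de,
    load_paper_fixture,
)


@pytest.fixture(scope="session")
def paper():
    """The packaged study fixture (transcribed result tables)."""
    return load_paper_fixture()


@pytest.fixture(scope="session")
def fixture_consensus(paper):
    """Consensus recomputed end to end from the fixture's derived inputs."""
    de = filter_de(list(paper.de_records))
    return consensus_interactions(
        de, paper.predictions_a, paper.predictions_b, paper.catalog
    )
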