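import pytest

from fusionomics import synth


@pytest.fixture(scope="session")
def sim_config():
    return synth.preset("full", seed=11)


@pytest.fixture(scope="session")
def toy_genome(sim_config):
    return synth.make_toy_genome(sim_config)


@pytest.fixture
def genes_two():
    """Two genes on opposite strands of one toy chromosome."""
    from fusionomics.core_io import GeneModel

    return [
        GeneModel("gA", "chr1", "+", 1000, 3000),
        GeneModel("gB", "chr1", "-", 20000, 22000),
    ]
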