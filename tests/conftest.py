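import pytest

from viroscan import catalog as cat
from viroscan import simulate as sim


@pytest.fixture(scope="session")
def packaged_records():
    return cat.load_catalog(cat.packaged_catalog_path())


@pytest.fixture(scope="session")
def genome_10k():
    return sim.simulate_genome(10_000, gc=0.5, seed=1)


@pytest.fixture(scope="session")
def genome_1k():
    return sim.simulate_genome(1_000, gc=0.5, seed=2)
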