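import pytest

from pufascreen import simulate as sim


@pytest.fixture(scope="session")
def freshwater_sample():
    contigs, truth = sim.make_sample("freshwater", seed=7)
    return contigs, truth


@pytest.fixture(scope="session")
def marine_sample():
    contigs, truth = sim.make_sample("marine", seed=7)
    return contigs, truth


@pytest.fixture(scope="session")
def genome_fixture():
    scaffold_id, scaffold, gff3, truth = sim.make_genome_fixture(seed=1)
    return scaffold_id, scaffold, gff3, truth


@pytest.fixture(scope="session")
def cox1_panel():
    return sim.bundled_cox1_panel()
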