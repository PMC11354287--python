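import pytest

from plastevo import simulate as sim
from plastevo.structure import RegionPartition


@pytest.fixture(scope="session")
def type_I():
    return sim.build_type_I_plastome(seed=1, taxon_id="cladeA")


@pytest.fixture(scope="session")
def type_II(type_I):
    g = sim.apply_structural_events(type_I, sim.type_II_events())
    g.taxon_id = "cladeB"
    return g


@pytest.fixture(scope="session")
def type_III(type_I):
    g = sim.apply_structural_events(type_I, sim.type_III_events())
    g.taxon_id = "cladeC"
    return g


@pytest.fixture(scope="session")
def part_I(type_I):
    return RegionPartition.from_features(type_I)


@pytest.fixture(scope="session")
def part_II(type_II):
    return RegionPartition.from_features(type_II)


@pytest.fixture(scope="session")
def clade_tree():
    return sim.three_clade_tree(4)
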