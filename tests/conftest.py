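import pytest

from mitocompare.catalog import PCGS
from mitocompare.simulate import SimulationSpec, simulate_genome

#: tiny gene lengths for tests that only care about gene order
MINI_KW = dict(
    pcg_lengths={g: 12 for g in PCGS},
    trna_length=9, rrnl_length=12, rrns_length=12, cr_length=9,
)


@pytest.fixture(scope="session")
def default_spec() -> SimulationSpec:
    return SimulationSpec(seed=11)


@pytest.fixture(scope="session")
def base_genome(default_spec):
    """Full-size synthetic genome in the ancestral arrangement."""
    return simulate_genome(default_spec, 0)


@pytest.fixture(scope="session")
def mini_spec() -> SimulationSpec:
    return SimulationSpec(seed=11, **MINI_KW)


@pytest.fixture(scope="session")
def mini_genome(mini_spec):
    """Miniature 37-gene genome for rearrangement tests."""
    return simulate_genome(mini_spec, 0)
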