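import pytest

from lncevo.formats import read_newick_dated
from lncevo.simulate import SimulationConfig


@pytest.fixture
def toy_tree():
    """Three-taxon dated tree: ((A:10,B:10):90,C:100);"""
    return read_newick_dated("((A:10,B:10):90,C:100);")


@pytest.fixture
def small_config():
    """A quick-running simulation with the default per-stage behaviour."""
    return SimulationConfig(
        seed=11,
        n_species=6,
        n_families=10,
        n_orphans_per_species=3,
        n_expression_genes=80,
    )
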